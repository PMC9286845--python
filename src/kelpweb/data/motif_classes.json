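{
  "comment": "Canonical adjacency (edge lists, consumer->resource) of the 13 connected three-node digraph classes. S classes have no mutually-consuming pair; D classes have at least one.",
  "classes": [
    {"label": "S1", "edges": [[0, 1], [1, 2]], "description": "three-species chain"},
    {"label": "S2", "edges": [[0, 1], [0, 2], [1, 2]], "description": "omnivory / intraguild predation"},
    {"label": "S3", "edges": [[0, 1], [1, 2], [2, 0]], "description": "directed trophic loop"},
    {"label": "S4", "edges": [[0, 2], [1, 2]], "description": "apparent competition (shared resource)"},
    {"label": "S5", "edges": [[0, 1], [0, 2]], "description": "exploitative competition (shared consumer)"},
    {"label": "D1", "edges": [[0, 1], [1, 0], [0, 2], [1, 2]], "description": "mutual pair sharing a resource"},
    {"label": "D2", "edges": [[0, 1], [1, 0], [2, 0], [2, 1]], "description": "mutual pair sharing a consumer"},
    {"label": "D3", "edges": [[0, 1], [1, 0], [0, 2]], "description": "mutual pair, one member consuming a third"},
    {"label": "D4", "edges": [[0, 1], [1, 0], [2, 0]], "description": "mutual pair, one member consumed by a third"},
    {"label": "D5", "edges": [[0, 1], [1, 0], [0, 2], [2, 1]], "description": "mutual pair on a directed loop"},
    {"label": "D6", "edges": [[0, 1], [1, 0], [0, 2], [2, 0]], "description": "two mutual pairs"},
    {"label": "D7", "edges": [[0, 1], [1, 0], [0, 2], [2, 0], [1, 2]], "description": "two mutual pairs plus a single link"},
    {"label": "D8", "edges": [[0, 1], [1, 0], [0, 2], [2, 0], [1, 2], [2, 1]], "description": "complete mutual triangle"}
  ]
}
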