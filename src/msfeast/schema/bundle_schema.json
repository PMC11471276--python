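{
  "$id": "msfeast-bundle/1",
  "type": "object",
  "required": [
    "schema_version",
    "settings",
    "groups",
    "reference_group",
    "contrasts",
    "nodes",
    "edges",
    "clusters",
    "heatmap"
  ],
  "properties": {
    "schema_version": {"type": "string", "enum": ["msfeast-bundle/1"]},
    "settings": {"type": "object"},
    "groups": {"type": "object"},
    "reference_group": {"type": "string"},
    "contrasts": {"type": "array", "items": {"type": "string"}},
    "nodes": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["feature_id", "x", "y", "cluster_id", "stats"],
        "properties": {
          "feature_id": {"type": "string"},
          "x": {"type": "number"},
          "y": {"type": "number"},
          "cluster_id": {"type": "string"},
          "stats": {"type": "object"}
        }
      }
    },
    "edges": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["source_id", "target_id", "rank", "similarity", "bin"],
        "properties": {
          "source_id": {"type": "string"},
          "target_id": {"type": "string"},
          "rank": {"type": "integer", "minimum": 1},
          "similarity": {"type": "number", "minimum": 0, "maximum": 1},
          "bin": {"type": "string", "enum": ["weak", "moderate", "strong"]}
        }
      }
    },
    "clusters": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["cluster_id", "members", "medoid", "silhouette"],
        "properties": {
          "cluster_id": {"type": "string"},
          "members": {"type": "array", "items": {"type": "string"}},
          "medoid": {"type": "string"},
          "silhouette": {"type": "number", "minimum": -1, "maximum": 1}
        }
      }
    },
    "heatmap": {
      "type": "object",
      "required": ["cluster_ids", "contrasts", "p_raw", "p_adjusted", "significant"],
      "properties": {
        "cluster_ids": {"type": "array", "items": {"type": "string"}},
        "contrasts": {"type": "array", "items": {"type": "string"}},
        "p_raw": {"type": "array"},
        "p_adjusted": {"type": "array"},
        "significant": {"type": "array"}
      }
    }
  }
}
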