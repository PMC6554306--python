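{
  "title": "TgINDEL report",
  "required": {
    "meta": {"type": "object"},
    "deletion": {
      "type": "object",
      "required": {
        "length": {},
        "depth_ratio": {"type": "number"}
      }
    },
    "zygosity": {"type": "string"},
    "junctions": {"type": "array"},
    "orientation_switch": {
      "type": "object",
      "required": {
        "detected": {"type": "boolean"},
        "position_in_array_resolved": {"type": "boolean"}
      }
    },
    "copy_number": {"type": "object"}
  }
}
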