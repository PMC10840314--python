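{
  "title": "saskit run summary",
  "required": ["schema_version", "status", "stages", "config"],
  "properties": {
    "schema_version": "integer",
    "status": "string",
    "stages": "object",
    "config": "object",
    "guinier": "object",
    "mw": "object",
    "pr": "object",
    "buffer_report": "object",
    "sample_report": "object"
  }
}
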