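[
  {"item_id": "art-001", "kind": "article", "domains": ["walking", "general_activities"], "title": "Staying active with cardiac pain"},
  {"item_id": "art-002", "kind": "lay_summary", "domains": ["mood"], "title": "Mood and the heart: what the evidence says"},
  {"item_id": "art-003", "kind": "lay_summary", "domains": ["sleep"], "title": "Sleep strategies when pain keeps you up"},
  {"item_id": "art-004", "kind": "article", "domains": ["work"], "title": "Returning to work after a cardiac event"},
  {"item_id": "vid-001", "kind": "video", "domains": ["mood", "relations"], "title": "Talking to loved ones about your symptoms"},
  {"item_id": "vid-002", "kind": "video", "domains": ["walking"], "title": "Gentle walking routines"},
  {"item_id": "pod-001", "kind": "podcast", "domains": ["enjoyment", "mood"], "title": "Finding joy while managing chronic symptoms"},
  {"item_id": "pod-002", "kind": "podcast", "domains": ["sleep", "general_activities"], "title": "Pacing your day, resting your night"}
]
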