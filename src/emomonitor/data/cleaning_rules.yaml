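# Adaptation rules for pandemic-period social-media text, applied on top of
# the emotion lexicon before scoring. Four groups:
#   (1) words used far more often by news media during the pandemic without
#       expressing the emotion (death/killing/healing/service vocabulary),
#   (2) mismatches unrelated to the emotion picked up by stems,
#   (3) Austria-specific proper nouns and events caught by stems,
#   (4) platform-mechanic words, dropped only when scoring Twitter.
# Items printed as whole patterns are removed outright; single tokens that a
# legitimately kept stem would match become per-category exceptions.

# (1) pandemic-frequency words
- {action: remove_entry, category: sad, target: "tot*", platform_scope: all}
- {action: remove_entry, category: anger, target: "toete*", platform_scope: all}
- {action: remove_entry, category: anger, target: "töt*", platform_scope: all}
- {action: remove_entry, category: anger, target: "töte*", platform_scope: all}
- {action: remove_entry, category: posemo, target: "heilte", platform_scope: all}
- {action: remove_entry, category: posemo, target: "geheilt", platform_scope: all}
- {action: remove_entry, category: posemo, target: "heilt", platform_scope: all}
- {action: remove_entry, category: posemo, target: "heilte*", platform_scope: all}
- {action: remove_entry, category: posemo, target: "heilung", platform_scope: all}
- {action: remove_entry, category: prosocial, target: "heilverfahren", platform_scope: all}
- {action: remove_entry, category: prosocial, target: "behandlung", platform_scope: all}
- {action: remove_entry, category: prosocial, target: "behandlungen", platform_scope: all}
- {action: remove_entry, category: prosocial, target: "öffentlicher dienst", platform_scope: all}
- {action: remove_entry, category: prosocial, target: "digitale dienste", platform_scope: all}
- {action: add_exception, category: prosocial, target: "dienstpflicht", platform_scope: all}

# (2) mismatches unrelated to the emotion
- {action: add_exception, category: sad, target: "harmonie", platform_scope: all}
- {action: add_exception, category: sad, target: "harmlos", platform_scope: all}
- {action: remove_entry, category: posemo, target: "äußerst", platform_scope: all}
- {action: add_exception, category: prosocial, target: "dienstag", platform_scope: all}

# (3) Austria-specific terms
- {action: add_exception, category: sad, target: "klagenfurt", platform_scope: all}
- {action: add_exception, category: sad, target: "misstrauensantrag", platform_scope: all}

# (4) Twitter-mechanic words, Twitter analyses only
- {action: remove_entry, category: prosocial, target: "teilen", platform_scope: twitter}
- {action: remove_entry, category: prosocial, target: "teilt mit", platform_scope: twitter}
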