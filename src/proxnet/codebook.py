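"""Packaged survey codebook: item codes, response ranges, retained sets.

Two multi-item scales (community attitude, 9 items; openness, 5 items)
answered on 1--5 agreement scales, plus three single items: reported
participation in community activities (1--5), happiness and subjective
health (0--10).  Retention combines a loading threshold with an explicit
manual-exclusion list: ``pc_participate`` is excluded from the community
composite on theoretical grounds (it is analyzed as a separate item)
even though its loading can clear the numeric threshold.
"""

DEFAULT_LOADING_THRESHOLD = 0.45

SCALES = {
    "pro_community": {
        "label": "Pro-community attitude",
        "items": [
            "pc_attachment",     # attachment to the community
            "pc_tradition",      # valuing local traditions
            "pc_trust",          # trust toward members
            "pc_honesty",        # perceived honesty of members
            "pc_rules",          # following community rules
            "pc_help",           # helping members in need
            "pc_treat",          # treating/hosting neighbors
            "pc_participate",    # participation in community activities
            "pc_no_refuse",      # felt obligation to reciprocate
        ],
        "range": (1, 5),
        "manual_exclusions": ["pc_participate"],
        # published retained set for this scale (7 of 9 items)
        "retained": [
            "pc_attachment", "pc_tradition", "pc_trust", "pc_honesty",
            "pc_rules", "pc_help", "pc_treat",
        ],
    },
    "openness": {
        "label": "Openness",
        "items": [
            "op_outside_values",   # welcoming outside values/ideas
            "op_new_culture",      # creating new culture beyond tradition
            "op_foreign_settler",  # welcoming settlers from abroad
            "op_outside_settler",  # welcoming settlers from elsewhere
            "op_problems",         # expected problems from newcomers (reverse-keyed)
        ],
        "range": (1, 5),
        "manual_exclusions": [],
        # published retained set for this scale (4 of 5 items)
        "retained": [
            "op_outside_values", "op_new_culture",
            "op_foreign_settler", "op_outside_settler",
        ],
    },
}

SINGLE_ITEMS = {
    "participation": {"item": "pc_participate", "range": (1, 5),
                      "label": "Participation in community activities"},
    "happiness": {"item": "happiness", "range": (0, 10), "label": "Happiness"},
    "subjective_health": {"item": "subjective_health", "range": (0, 10),
                          "label": "Subjective health"},
}

ALL_ITEMS = (
    SCALES["pro_community"]["items"]
    + SCALES["openness"]["items"]
    + ["happiness", "subjective_health"]
)
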