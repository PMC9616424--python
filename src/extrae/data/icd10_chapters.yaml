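# ICD-10 chapter buckets keyed by the first character of the code.
# The official chapters are merged/split into 24 buckets; the two classic
# letter-sharing chapters (A/B infectious, S/T injury) are merged and every
# other initial letter gets its own bucket.  Order is frozen: it defines the
# 24 chapter-count feature columns, so trained models remain portable.
# Replace this file to use a different chapter grouping (24 buckets required
# by the feature contract).
buckets:
  - name: infectious          # A00-B99
    chars: [A, B]
  - name: neoplasms           # C00-C97
    chars: [C]
  - name: blood_immune        # D00-D89
    chars: [D]
  - name: endocrine_metabolic # E00-E90
    chars: [E]
  - name: mental_behavioural  # F00-F99
    chars: [F]
  - name: nervous_system      # G00-G99
    chars: [G]
  - name: eye_ear             # H00-H95
    chars: [H]
  - name: circulatory         # I00-I99
    chars: [I]
  - name: respiratory         # J00-J99
    chars: [J]
  - name: digestive           # K00-K93
    chars: [K]
  - name: skin                # L00-L99
    chars: [L]
  - name: musculoskeletal     # M00-M99
    chars: [M]
  - name: genitourinary       # N00-N99
    chars: [N]
  - name: pregnancy           # O00-O99
    chars: [O]
  - name: perinatal           # P00-P96
    chars: [P]
  - name: congenital          # Q00-Q99
    chars: [Q]
  - name: symptoms_findings   # R00-R99
    chars: [R]
  - name: injury_poisoning    # S00-T98
    chars: [S, T]
  - name: special_purposes    # U00-U99
    chars: [U]
  - name: external_transport  # V01-V99
    chars: [V]
  - name: external_other_w    # W00-W99
    chars: [W]
  - name: external_other_x    # X00-X99
    chars: [X]
  - name: external_other_y    # Y00-Y98
    chars: [Y]
  - name: health_factors      # Z00-Z99
    chars: [Z]
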