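# Three illustrative disease archetypes for `idda simulate --config`.
# presence_probs are 17 probabilities in the fixed kaleidoscope axis order
# (items 1-14, then other organ dysfunction, Ig substitution, malignancy).
# Values are illustrative, not calibrated to any published cohort.
archetypes:
- name: tregopathy
  presence_probs: [0.90, 0.30, 0.85, 0.70, 0.40, 0.70, 0.20, 0.75, 0.30, 0.35,
                   0.30, 0.25, 0.60, 0.50, 0.30, 0.50, 0.10]
  hosp_rate: 12.0
  icu_rate: 1.5
- name: cvid-like
  presence_probs: [0.25, 0.05, 0.30, 0.50, 0.65, 0.25, 0.45, 0.10, 0.20, 0.15,
                   0.10, 0.10, 0.15, 0.85, 0.25, 0.95, 0.15]
  hosp_rate: 6.0
  icu_rate: 0.5
- name: ebv-pird
  presence_probs: [0.35, 0.80, 0.15, 0.90, 0.15, 0.10, 0.05, 0.05, 0.05, 0.30,
                   0.05, 0.30, 0.30, 0.70, 0.20, 0.35, 0.55]
  hosp_rate: 15.0
  icu_rate: 3.0
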