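# Default immune-epitope-curation disease-category tree.
#
# Only the published nodes are shipped: the seven Level-1 disease areas,
# Autoimmunity's seven Level-2 sub-diseases, and the seven Level-3
# antigen/topic categories under Diabetes.  Other branches (e.g. the
# Infectious Disease Level-2 pathogens) must be supplied by user config.
#
# skip_levels: Transplantation and Cancer references receive no Level-2
# category (their children, when configured, sit at Level 3); HIV
# references receive neither Level-2 nor Level-3 categories.
level1:
  - name: Allergy
    priority: high
  - name: Autoimmunity
    priority: high
    children:
      - name: Beta-Amyloid
      - name: Diabetes
        children:
          - name: GAD
          - name: HSP
          - name: IA2
          - name: IGRP
          - name: INSULIN
          - name: OTH
            catch_all: true
          - name: VAR
            catch_all: true
      - name: General Autoimmune
      - name: Lupus
      - name: Multiple Sclerosis
      - name: Myasthenia Gravis
      - name: Rheumatoid Arthritis
  - name: Infectious Disease
    priority: high
  - name: Transplantation
    priority: high
    skip_levels: [2]
  - name: Cancer
    priority: low
    skip_levels: [2]
  - name: HIV
    priority: low
    skip_levels: [2, 3]
  - name: Other
    priority: low
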