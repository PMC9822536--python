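# Local registry of known GENIE BPC data releases.
# `sequence` orders releases within a cohort; `access` defaults to the
# version suffix (-public / -consortium). Edit or replace to track new
# releases; this file is the offline source of truth for `bpc versions`.
releases:
  - cohort: BrCa
    version: v1.1-consortium
    release_date: October 2021
    sequence: 2
  - cohort: BrCa
    version: v1.0-consortium
    release_date: April 2021
    sequence: 1
  - cohort: CRC
    version: v1.2-consortium
    release_date: August 2021
    sequence: 2
  - cohort: CRC
    version: v1.1-consortium
    release_date: March 2021
    sequence: 1
  - cohort: NSCLC
    version: v2.1-consortium
    release_date: August 2021
    sequence: 3
  - cohort: NSCLC
    version: v2.0-consortium
    release_date: March 2021
    sequence: 2
  - cohort: NSCLC
    version: v1.1-consortium
    release_date: October 2020
    sequence: 1
  - cohort: NSCLC
    version: v2.0-public
    release_date: May 2022
    sequence: 4
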