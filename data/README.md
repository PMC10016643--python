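# data/

Optional external inputs.

`s1_table.csv` — the original study's per-bird supplementary table (S1:
genetic assignment, feather d2H, harvest date, sex for 296 hatch-year
mallards), converted from the publisher's XLSX to CSV. When present, the
acceptance test reproducing the published isotope statistics
(`tests/test_acceptance.py::test_criterion_3_s1_table_reproductions`) and
`mallardpipe.originstats.load_s1_table` can use it. Expected columns (common
aliases accepted): sample_id, d2hf, day (days since 4 October), sex, klass.

Nothing in this directory is required to run the pipeline or the rest of the
test suite; all other inputs are generated by `mallardpipe.synthio`.
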