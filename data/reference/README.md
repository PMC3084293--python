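# Deposited reference coordinates

This directory holds the deposited coordinate sets used by the
reference analyses and the deposited-entry acceptance tests:

| entry | contents |
|-------|----------|
| 3asi  | Nrx1α LNS5-EGF3-LNS6 fragment |
| 1c4r  | Nrx1β LNS domain |
| 1dyk  | laminin α2 LNS5 domain |
| 3b3q  | Nrx1β/neuroligin-1 2:2 complex |
| 3biw  | Nrx1β/neuroligin-1 2:2 complex |

The files are not redistributed with the package. Populate the
directory with

    python analysis/01_fetch_reference.py

(requires network access to files.rcsb.org). Without these files the
synthetic test suite and benchmarks run unaffected; the
deposited-entry tests in `tests/test_acceptance.py` fail with a
message pointing here, and the reference analysis scripts print the
same pointer and exit cleanly.
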