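# data/

Deposited inputs consumed by two end-to-end checks; not redistributed here.

- `asclepias_nuclear_contigs.fasta` — the published supplementary FASTA of
  nuclear de novo assembly contigs (study supplementary file 5; also at
  milkweedgenome.org).  Used to verify the >= 150 bp contig count (2,624)
  and as a soft cross-check of the SSR scanner against the published 395.
- `JF433943.fasta` — the finished chloroplast genome (GenBank JF433943,
  158,598 bp).  Used to verify the detected inverted-repeat length
  (25,401 bp).

The corresponding tests in `tests/test_acceptance.py` fail with a clear
message while these files are absent.
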