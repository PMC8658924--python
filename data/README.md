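# data/

Place `GSE6432_series_matrix.txt.gz` (or the uncompressed `.txt`) here to
enable the exact-replication acceptance test and the full acceptance report;
download it from the Series Matrix File(s) section of GEO accession GSE6432.
Nothing in this directory is required for the synthetic-data test suite.
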