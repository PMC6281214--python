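Place the published per-sample supplementary workbook here as
per_sample_table.xlsx (XLSX, one sheet per chromosome 13/18/21 with the six
Z scores, upstream run Z, confirmed state and grouping) to enable the
supplementary reproduction test. The file is third-party clinical data and
is not bundled with this package.
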