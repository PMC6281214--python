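"""The on-disk formats: grid, per-sample counts, metadata, panel, report.

Writes a simulated cohort to TSV files, reads everything back through
the documented loaders, builds and saves a reference panel, and writes a
screening report -- the same round trip the command-line interface
(`niptcall simulate/reference/report ...`) drives from the shell.
"""

import tempfile
from pathlib import Path

from niptcall import (ResultRow, SimConfig, build_reference_panel,
                      normalize_pipeline, read_bin_counts, read_bin_grid,
                      read_panel, read_report, read_sample_metadata,
                      simulate_cohort, write_bin_counts, write_bin_grid,
                      write_panel, write_report, write_sample_metadata)

cfg = SimConfig(n_bins_total=3000, n_ref=5, n_train_neg=2,
                n_train_pos_per_chrom=0, n_grey_pos_per_chrom=0,
                n_grey_neg=0, n_qcfail=0)
cohort = simulate_cohort(cfg, seed=3)

with tempfile.TemporaryDirectory() as tmp:
    tmp = Path(tmp)
    write_bin_grid(cohort.grid, tmp / "grid.tsv")
    write_sample_metadata(cohort.records.values(), tmp / "meta.tsv")
    count_files = []
    for i, sid in enumerate(cohort.depth.sample_ids):
        path = tmp / f"{sid}.tsv"
        write_bin_counts(cohort.depth.values[i], cohort.grid, path)
        count_files.append(path)

    grid = read_bin_grid(tmp / "grid.tsv")
    depth = read_bin_counts(count_files, grid)
    records = read_sample_metadata(tmp / "meta.tsv")
    print(f"grid: {grid.n_usable} usable bins, fingerprint {grid.fingerprint()}")
    print(f"depth matrix: {depth.values.shape[0]} samples x "
          f"{depth.values.shape[1]} bins; {len(records)} metadata records")

    profiles = normalize_pipeline(depth)
    panel = build_reference_panel(profiles[:5])
    write_panel(panel, tmp / "panel.tsv")
    panel = read_panel(tmp / "panel.tsv")
    print("panel chr21: mean {:.4f}, sd {:.4f} over {} negatives".format(
        panel.ref_mean["21"], panel.ref_sd["21"], panel.n_ref))

    rows = [ResultRow(sample_id=p.sample_id, chrom="21",
                      features=tuple(float(i) for i in range(10)),
                      qc_flag="pass", triage_group="N", predicted_class=-1,
                      probability_negative=0.99, probability_positive=0.01)
            for p in profiles[5:]]
    write_report(rows, tmp / "report.tsv")
    print(f"report: {len(read_report(tmp / 'report.tsv'))} rows round-tripped")
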