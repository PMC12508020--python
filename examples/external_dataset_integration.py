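"""Full pipeline on a real mouse-tracking dataset (requires a download).

This script is NOT part of the test suite: it needs an externally obtained
long-format CSV of a two-option tracking study (for instance a public
60-subject animal-categorization dataset exported to CSV with columns
subject_nr, count_trial, Condition, correct, timestamps, xpos, ypos).

Run:
    python examples/external_dataset_integration.py path/to/raw_long.csv

It reproduces the headline statistics of that study design: the chi-square
test on prototype-mapped type frequencies by typicality condition, and the
near-unity correlation between MAD and MD_above.
"""

import sys

import pandas as pd

import reachtrace as rt


def main(path: str) -> None:
    raw = pd.read_csv(path)
    id_cols = [c for c in ("subject_nr", "count_trial", "trial_id")
               if c in raw.columns]
    ds = rt.import_long(raw, id_cols, screen_y_down="ypos_down" in raw.columns)
    if "correct" in ds.trial_table.columns:
        ds = rt.subset(ds, "correct == 1")
    ds = rt.remap_symmetric(ds)
    ds = rt.align_start(ds)
    ds = rt.time_normalize(ds, n_steps=101)
    ds = rt.length_normalize(ds, n_points=20)

    measures = rt.add_sample_entropy(ds, rt.compute_measures(ds))
    corr = rt.index_correlation_report(measures)
    print(f"r(MAD, MD_above) = {corr.loc['MAD', 'MD_above']:.2f}")
    print(f"r(AUC, AD)       = {corr.loc['AUC', 'AD']:.2f}")

    mapped = rt.map_to_prototypes(ds)
    group = "Condition" if "Condition" in ds.trial_table.columns else None
    if group:
        table = rt.type_frequency_table(mapped, ds.trial_table, group,
                                        labels=rt.TYPE_ORDER)
        res = rt.chi_square_independence(table)
        print(table.to_string())
        print(f"chi2({res.df}) = {res.chi2:.2f}, p = {res.p:.2g}")
        print(res.pearson_residuals.round(2).to_string())


if __name__ == "__main__":
    if len(sys.argv) != 2:
        sys.exit(__doc__)
    main(sys.argv[1])
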