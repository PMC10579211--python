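#!/usr/bin/env python
"""Statistical comparisons across reconstructions.

Clinical arm: one-way repeated-measures ANOVA over the 45 x 6 SUVmax matrix
(subject = lesion) with Bonferroni-corrected paired-t post hocs.  Phantom
arm: paired t per metric between adjacent reconstructions across the six
spheres (reads the tables from 02_reconstruct_sweep.py).
"""

from pathlib import Path

import pandas as pd

from petiq.clinical import RECON_IDS, lesion_table
from petiq.stats import paired_t, repeated_anova_bonferroni

IN = Path("results/sweeps")
OUT = Path("results/stats")


def result_row(t, **extra):
    return {"comparison": t.comparison, "statistic": t.statistic,
            "p": t.p_value, "adjusted_p": t.adjusted_p,
            "significant": t.significant, "n": t.n} | extra


def main():
    OUT.mkdir(parents=True, exist_ok=True)

    mat = lesion_table()[list(RECON_IDS)]
    anova, posthocs = repeated_anova_bonferroni(mat)
    rows = [result_row(anova, arm="clinical", metric="suvmax")]
    rows += [result_row(t, arm="clinical", metric="suvmax") for t in posthocs]
    print(f"clinical RM-ANOVA: F = {anova.statistic:.1f}, "
          f"p = {anova.p_value:.3g} over {anova.n} lesions x 6 reconstructions")
    sig = [t.comparison for t in posthocs if t.significant]
    print(f"Bonferroni-significant pairs ({len(sig)}/{len(posthocs)}): {sig}")

    adjacent = [("beta100", "beta200"), ("beta200", "beta300"),
                ("beta300", "beta400"), ("beta400", "beta500"),
                ("beta500", "OSEM")]
    for lbr in (2, 4, 8):
        path = IN / f"sphere_metrics_lbr{lbr}.csv"
        if not path.exists():
            print(f"skipping phantom stats for LBR {lbr} (run 02 first)")
            continue
        sph = pd.read_csv(path)
        for metric in ("CR", "SNR", "suvmax"):
            wide = sph.pivot(index="diameter_mm", columns="recon", values=metric)
            for a, b in adjacent:
                t = paired_t(wide[a], wide[b], label=f"{a} vs {b}",
                             n_comparisons=len(adjacent))
                rows.append(result_row(t, arm="phantom", metric=metric, lbr=lbr))

    pd.DataFrame(rows).to_csv(OUT / "tests.csv", index=False)
    print(f"wrote {OUT}/tests.csv")


if __name__ == "__main__":
    main()
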