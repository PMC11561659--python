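"""Worked statistical examples computable from published summary numbers.

Pools the per-group age summaries into whole-cohort mean/SD, compares the
occipital soma-fraction-age correlation against the volume-age
correlation via Fisher r-to-z, and demonstrates the quadratic-trend
machinery; writes results/worked_examples.json.
"""

import json
from pathlib import Path

import numpy as np

from sandimri.stats import fisher_z_compare, polynomial_age_fit

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)


def main():
    groups = ((33, 25.5, 3.6), (21, 44.3, 6.6), (18, 67.1, 7.7))
    n = sum(g[0] for g in groups)
    mean = sum(g[0] * g[1] for g in groups) / n
    ss = sum((g[0] - 1) * g[2] ** 2 + g[0] * (g[1] - mean) ** 2
             for g in groups)
    sd = float(np.sqrt(ss / (n - 1)))
    print(f"Pooled cohort age: {mean:.1f} +/- {sd:.1f} years (n={n})")

    z, p = fisher_z_compare(-0.69, 72, -0.31, 72)
    print(f"Occipital soma-fraction-age (r=-0.69) vs volume-age (r=-0.31), "
          f"n=72: z = {z:.2f}, p = {p:.3f} — microstructure beats "
          "macrostructure there")

    age = np.linspace(19, 85, 72)
    trend = polynomial_age_fit(age, -((age - 55.0) ** 2))
    print(f"Noiseless inverted-U check: peak age {trend.peak_age:.1f}, "
          f"quadratic R^2 = {trend.r2_quadratic:.3f}")

    (OUT / "worked_examples.json").write_text(json.dumps({
        "pooled_age_mean": round(mean, 4), "pooled_age_sd": round(sd, 4),
        "occipital_fisher_z": round(z, 4), "occipital_fisher_p": round(p, 4),
        "quadratic_peak_age": trend.peak_age,
    }, indent=2) + "\n")


if __name__ == "__main__":
    main()
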