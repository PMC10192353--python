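"""The screen's characterization statistics on small worked inputs."""

import pandas as pd

from fundusmap import (
    iqr_outliers,
    lipid_ratios,
    percent_change,
    saturation,
    trend_regression,
)

# IQR outlier exclusion (Tukey fences)
kept, removed, bounds = iqr_outliers([12, 14, 15, 16, 18, 55])
print(f"cell counts {[12, 14, 15, 16, 18, 55]}: fences {bounds[0]:.1f}..{bounds[1]:.1f}, removed {removed.tolist()}")

# percent change: male weight at 9-14 months
pct = percent_change(38.4, 32.9, round_to_int=True)
print(f"weight 38.4 g -> 32.9 g: {pct:+.0f}% (a 14% decrease)")

# age trend of fundus-spot scores
ages = [2, 3, 4, 6, 8, 10, 12, 13]
scores = [1, 3, 4, 5, 6, 6, 7, 8]
fit = trend_regression(ages, scores)
print(f"score-vs-age trend: slope {fit.slope:.2f}/month, R2 {fit.R2:.3f}, F {fit.F:.1f}, p {fit.p:.2e}")

# lipid-class ratios per tissue
samples = pd.DataFrame(
    {
        "sample_id": [f"s{i}" for i in range(4)],
        "tissue": ["retina"] * 4,
        "group": ["wt", "wt", "ko", "ko"],
        "TAG": [2.0, 2.2, 4.5, 5.0],
        "DAG": [1.0, 1.1, 1.0, 0.9],
        "Chl": [3.0, 2.8, 2.5, 2.4],
        "CE": [0.5, 0.6, 1.4, 1.5],
    }
)
ratios, tests = lipid_ratios(samples)
print("\nTAG/(TAG+DAG) per sample:")
print(ratios[["sample_id", "group", "TAG_over_TAG_plus_DAG"]].round(3).to_string(index=False))

# genome saturation
genes = pd.DataFrame(
    {
        "gene": ["g1", "g2", "g3", "g4"],
        "effect_class": ["probably_null", "probably_damaging", "probably_damaging", "probably_benign"],
        "n_VAR_mice_screened": [3, 2, 1, 9],
    }
)
frac = saturation(genes, gene_universe_size=100)
print(f"\nsaturation: {frac:.2%} of a 100-gene universe "
      "(damaging allele AND >= 2 homozygotes screened)")
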