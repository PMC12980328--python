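"""Explaining a nonlinear gene pair with sample metadata.

The group-masked motif mimics a sex-linked gene: exactly zero in one group,
expressed in the other. Correlating the gene with the categorical group
label (possible because the coefficient partitions categories directly)
returns 1.0 — the metadata variable fully explains the pattern — while an
unrelated numerical covariate (age) stays at noise level.
"""

import pandas as pd

from cccoef import (
    CccConfig,
    FeatureVector,
    generate_dataset,
    metadata_associations,
)

ds = generate_dataset(1, n_null_features=0, n_samples=200, seed=1234)
feats = [
    FeatureVector.from_numerical(str(f), ds.expression.loc[f].to_numpy())
    for f in ds.expression.index
]
meta_feats = [
    FeatureVector.from_categorical("sex", ds.metadata["group"].tolist()),
    FeatureVector.from_categorical("cohort", ds.metadata["cohort"].tolist()),
    FeatureVector.from_numerical("age", ds.metadata["age"].to_numpy()),
]

pairs = pd.DataFrame(
    {
        "feature_i": ["group_masked_0_x", "cohort_shift_0_x"],
        "feature_j": ["group_masked_0_y", "cohort_shift_0_y"],
    }
)
out = metadata_associations(pairs, feats, meta_feats,
                            CccConfig(n_perm=99, seed=0))
print(out.to_string(index=False))
print()
print("The masked gene vs 'sex' and the shifted pair vs 'cohort' score at or")
print("near 1 with the smallest attainable p-value (1/100). 'age' stays at")
print("noise-level ccc for every gene (its p-values are uniform draws, so an")
print("occasional small one carries no effect size behind it), as designed.")
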