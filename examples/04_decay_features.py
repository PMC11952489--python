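"""Decay-covariate feature engineering and the resampled LASSO harness.

Builds a synthetic isoform feature table in which one feature truly drives
log(kdeg), encodes numeric and categorical columns, and shows that the
bootstrap LASSO assigns it a stable coefficient while decoys shrink to zero.
Also demonstrates the translation-initiation (Kozak) window scorer.
"""

import numpy as np
import pandas as pd

from isodeg.features import (
    encode_features, example_pssm, kozak_score, lasso_regress,
)

rng = np.random.default_rng(11)
n = 1500
raw = pd.DataFrame({
    "exon_count": rng.integers(1, 20, n).astype(float),
    "tx_length": rng.lognormal(8, 1, n),        # spans orders of magnitude
    "gc_content": rng.uniform(0.3, 0.7, n),
    "stop_codon": rng.choice(["UAA", "UAG", "UGA"], n),
})
# truth: more exons -> more stable (lower kdeg); everything else is noise
log_kdeg = pd.Series(-0.15 * raw["exon_count"] + rng.normal(0, 0.5, n))

encoded, encoder = encode_features(raw, log_kdeg, categorical=["stop_codon"])
print("encoded features (mean~0, sd~1):")
print(encoded.describe().loc[["mean", "std"]].round(3).to_string())

coefs = lasso_regress(encoded, log_kdeg, n_boot=50, seed=1)
print("\nbootstrap LASSO coefficient medians (on standardized features):")
print(coefs.median().round(3).to_string())
# exon_count should carry a clearly negative weight (stabilizing);
# the other columns should sit at ~0.

pssm = example_pssm()  # synthetic matrix, for demonstration only
for window in ("GCCGCCACCA", "TTTTTTTTTT"):
    print(f"\nKozak-window score of {window}: {kozak_score(window, pssm):+.2f}")
# the score sums one matrix entry per position; real analyses supply a
# matrix derived from measured initiation-context preferences.
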