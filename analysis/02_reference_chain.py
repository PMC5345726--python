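#!/usr/bin/env python
"""The packaged maximum-deviation matrix through the full pipeline.

Checks its stationary distribution, runs the SM and SL mutation-selection
chains, and reports the fourfold-usage deviation under both family
conventions (the five canonical families, and all eight fourfold boxes)
together with the matrix summaries (ti/tv ratio, reversibility deviation).
"""

from pathlib import Path

import numpy as np
import pandas as pd

from fourfold import experiments as ex
from fourfold.mutation import matrix_summary, stationary

OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(exist_ok=True)

P = ex.reference_matrix()
pi = stationary(P.probs)
print("reference matrix stationary distribution:", np.round(pi, 4))
s = matrix_summary(P)
print(f"ti/tv probability ratio {s.titv_ratio:.3f} (no-bias reference 0.5); "
      f"Dev_rev {s.dev_rev:.3f}")

rows = []
for variant in ("SM", "SL"):
    for family_set in ("canonical5", "boxes8"):
        dev = ex.reference_chain_deviation(variant, family_set)
        rows.append(
            {"variant": variant, "family_set": family_set,
             "F_total": round(dev.total, 4),
             **{f"F_{k}": round(v, 4) for k, v in dev.per_family.items()}}
        )
frame = pd.DataFrame(rows)
frame.to_csv(OUT / "reference_chain.tsv", sep="\t", index=False)
print("\n", frame.to_string(index=False))
print("""
The five-family statistic gives F ~ 4.9 under SM; summing all eight fourfold
boxes gives F ~ 9.2.  A published maximum of 9.10 for this matrix matches the
eight-box reading to within the matrix's printed precision, while the
published random-start baseline (~0.3) matches the five-family reading; the
two conventions cannot be reconciled and the package defaults to the five
canonical families (see docs/methods.md).""")
print(f"wrote {OUT / 'reference_chain.tsv'}")
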