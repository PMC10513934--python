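"""Score embedding quality with Moran's I conservation.

An embedding that retains biological variation gives smooth expression of
variable genes across its kNN graph (score near 1); destroying the pairing
between cells and coordinates drops the score to ~0.5 (the value of mean I = 0).
"""

import numpy as np
import pandas as pd
from anndata import AnnData

import isletkit as ik

rng = np.random.default_rng(0)
n, G = 1200, 900
embedding = rng.normal(size=(n, 5))
# expression of every gene is a smooth function of the first embedding axis
X = np.sin(rng.uniform(0.3, 1.5, G)[None, :] * embedding[:, :1]
           + rng.uniform(0, 2 * np.pi, G)[None, :]) + 1.0
adata = AnnData(X=X, obs=pd.DataFrame({"sample": np.repeat(["a", "b"], n // 2)},
                                      index=[f"c{i}" for i in range(n)]))
adata.layers["lognorm"] = X

res = ik.conservation_score(adata, embedding, g=800, k=15)
print(f"structured embedding: score = {res.score:.3f} (mean Moran's I = {res.mean_I:.3f})")

shuffled = ik.conservation_score(adata, embedding[rng.permutation(n)], g=800, k=15)
print(f"shuffled pairing:     score = {shuffled.score:.3f}")
# ~0.93 vs ~0.50: the metric separates informative from random embeddings
# without needing any cell-type annotation.
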