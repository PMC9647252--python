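"""Two-stage dimension reduction: PCA followed by a 2-D UMAP embedding.

The embedding is reporting-only; no downstream decision consumes the
coordinates.  Determinism is guaranteed by passing the seed through to both
stages.
"""

from __future__ import annotations

from typing import Union

import numpy as np
import pandas as pd

from .data import ValidationError, ZMatrix

__all__ = ["embed"]


def embed(z: Union[ZMatrix, pd.DataFrame], n_pcs: int = 20, seed: int = 0,
          n_neighbors: int = 15, min_dist: float = 0.1) -> pd.DataFrame:
    """PCA to ``n_pcs`` components, then UMAP to 2-D.

    Returns a DataFrame indexed by sample id with columns ``umap1``/``umap2``.
    """
    from sklearn.decomposition import PCA
    import umap

    zdf = z.z if isinstance(z, ZMatrix) else z
    n, p = zdf.shape
    if p < 2:
        raise ValidationError("embedding requires at least 2 species")
    k = min(n_pcs, n - 1, p)
    if k < 1:
        raise ValidationError("not enough samples for PCA")
    pcs = PCA(n_components=k, random_state=seed).fit_transform(
        zdf.to_numpy(dtype=float))
    reducer = umap.UMAP(n_components=2, random_state=seed,
                        n_neighbors=min(n_neighbors, n - 1), min_dist=min_dist)
    coords = reducer.fit_transform(pcs)
    return pd.DataFrame(coords, index=zdf.index, columns=["umap1", "umap2"])
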