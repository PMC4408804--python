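"""One-sample negative-binomial test of putative pri-miRNA regions.

RNA-seq (poly(A)-selected) is not a valid control outside mRNA regions,
so extended miRNA regions are scored without one: a single NB(mu, alpha)
is fitted by maximum likelihood over the CLIP read totals of all
surviving regions, each region gets the strict upper tail
P(X > x | mu, alpha), and p-values are Benjamini-Hochberg adjusted.

Region counts are raw totals of strand-matched CLIP reads (pri-miRNAs
are single-stranded transcripts).  An exposure offset for region length
is available but off by default.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import DataError
from .nbfit import NBOneSampleFit, fit_nb_one_sample
from .stats import bh_adjust, nb_tail


def score_mirna_regions(
    regions: pd.DataFrame,
    counts,
    fit: NBOneSampleFit | None = None,
    min_regions: int = 20,
    length_offset: bool = False,
) -> tuple[pd.DataFrame, NBOneSampleFit]:
    """Score each region against the global one-sample NB fit.

    ``regions`` is the miRNA-region frame (mirna_name, chrom, start, end,
    strand, ...); ``counts`` the matching vector of CLIP read totals.
    With ``length_offset`` the per-region mean is scaled by region length
    relative to the mean length, compensating truncation-induced length
    differences.  Returns (results sorted by adjusted p, fit).
    """
    x = np.asarray(counts, dtype=np.int64)
    if len(x) != len(regions):
        raise DataError("counts and regions length mismatch")
    if fit is None:
        fit = fit_nb_one_sample(x, min_regions=min_regions)

    lengths = (regions["end"] - regions["start"]).to_numpy(dtype=float)
    if length_offset:
        mus = fit.mu * lengths / lengths.mean()
    else:
        mus = np.full(len(x), fit.mu)

    p = np.array([nb_tail(int(xi), float(mi), fit.alpha) for xi, mi in zip(x, mus)])
    out = regions.copy()
    out["x"] = x
    out["mu"] = mus
    out["alpha"] = fit.alpha
    out["p_value"] = p
    out["bh_q"] = bh_adjust(p)
    out = out.sort_values(
        ["bh_q", "p_value", "chrom", "start"], kind="mergesort"
    ).reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    return out, fit
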