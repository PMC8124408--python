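"""FPKM quantification and panicle-vs-seedling differential expression.

FPKM_{i,s} = count_{i,s} * 1e9 / (length_i * library_size_s).  With one
library per tissue (the study design has no replicates) the differential
test is an exact count-based contrast: conditional on the total
c_p + c_s, the panicle count is Binomial with success probability
N_p / (N_p + N_s) under the null of equal concentration — the
Audic–Claverie-style two-library comparison.  A Fisher-exact variant is
available.  Both are documented stand-ins for an unnamed upstream tool.
Multiple testing is controlled by Benjamini–Hochberg; the call requires
BOTH |fold change| beyond the threshold and q below the FDR level.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass
class ExpressionTable:
    """Counts, effective lengths, library sizes and derived FPKM.

    ``counts``: transcripts x samples; ``lengths``: spliced nt per
    transcript; ``lib_sizes``: total mapped fragments per sample.
    """

    counts: pd.DataFrame
    lengths: pd.Series
    lib_sizes: pd.Series
    fpkm: pd.DataFrame


def compute_fpkm(
    counts: pd.DataFrame,
    lengths: pd.Series,
    lib_sizes: pd.Series | None = None,
) -> ExpressionTable:
    """Exact FPKM from raw counts.

    Library sizes default to column sums.  A counted transcript without a
    length is a hard error.
    """
    if "transcript_id" in counts.columns:
        counts = counts.set_index("transcript_id")
    counts = counts.select_dtypes("number")
    missing = counts.index.difference(lengths.index)
    if len(missing):
        raise KeyError(f"no length for transcript(s): {list(missing)[:5]}")
    lengths = lengths.loc[counts.index].astype(float)
    if (lengths < 1).any():
        raise ValueError("effective lengths must be >= 1")
    if lib_sizes is None:
        lib_sizes = counts.sum(axis=0)
    lib_sizes = lib_sizes.astype(float)
    if (lib_sizes < 1).any():
        raise ValueError("library sizes must be >= 1")
    fpkm = counts.astype(float).div(lengths, axis=0).div(lib_sizes, axis=1) * 1e9
    return ExpressionTable(counts=counts, lengths=lengths,
                           lib_sizes=lib_sizes, fpkm=fpkm)


def log_matrix(table: ExpressionTable) -> pd.DataFrame:
    """Elementwise log10(FPKM + 1); zero FPKM maps to 0."""
    return np.log10(table.fpkm + 1.0)


def benjamini_hochberg(pvals: Sequence[float]) -> np.ndarray:
    """BH step-up adjusted p-values (monotone q >= p ordering preserved)."""
    return multipletests(np.asarray(pvals, dtype=float), method="fdr_bh")[1]


def differential_expression(
    table: ExpressionTable,
    panicle: str,
    seedling: str,
    epsilon: float = 0.01,
    fc_threshold: float = 2.0,
    alpha: float = 0.05,
    method: str = "binomial",
) -> pd.DataFrame:
    """Per-transcript panicle-vs-seedling DE calls.

    Fold change FC = (FPKM_p + eps) / (FPKM_s + eps).  Transcripts with
    zero counts in both samples are excluded from testing (``tested`` is
    False).  ``de`` is True iff (FC > threshold or FC < 1/threshold) and
    BH-adjusted q < alpha.
    """
    if method not in ("binomial", "fisher"):
        raise ValueError(f"unknown method {method!r}")
    c_p = table.counts[panicle].to_numpy()
    c_s = table.counts[seedling].to_numpy()
    n_p = float(table.lib_sizes[panicle])
    n_s = float(table.lib_sizes[seedling])
    null_p = n_p / (n_p + n_s)
    fpkm_p = table.fpkm[panicle].to_numpy()
    fpkm_s = table.fpkm[seedling].to_numpy()
    fc = (fpkm_p + epsilon) / (fpkm_s + epsilon)
    tested = (c_p + c_s) > 0
    pvals = np.ones(len(c_p))
    for i in np.flatnonzero(tested):
        total = int(c_p[i] + c_s[i])
        if method == "binomial":
            pvals[i] = stats.binomtest(int(c_p[i]), total, null_p).pvalue
        else:
            # 2x2: observed counts vs remaining library mass
            tab = [[int(c_p[i]), int(c_s[i])],
                   [int(n_p - c_p[i]), int(n_s - c_s[i])]]
            pvals[i] = stats.fisher_exact(tab)[1]
    q = np.full(len(c_p), np.nan)
    if tested.any():
        q[tested] = benjamini_hochberg(pvals[tested])
    de = tested & ((fc > fc_threshold) | (fc < 1.0 / fc_threshold)) & (q < alpha)
    return pd.DataFrame({
        "transcript_id": table.counts.index,
        "count_panicle": c_p,
        "count_seedling": c_s,
        "fpkm_panicle": fpkm_p,
        "fpkm_seedling": fpkm_s,
        "fold_change": fc,
        "p": np.where(tested, pvals, np.nan),
        "q": q,
        "tested": tested,
        "de": de,
    }).reset_index(drop=True)
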