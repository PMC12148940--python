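"""Paired protein/transcript fold-change integration.

Combines per-gene differential tables from proteomics and RNA-seq to
find genes whose protein level changes while the transcript does not
(e.g. proteins retained in aged neurons despite normal mRNA), and tests
whether a gene set — RNA-binding proteins — is shifted as a set relative
to all other proteins.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .stats import TestResult, bh_fdr, welch_t_test, welch_t_test_rows

logger = logging.getLogger(__name__)

__all__ = [
    "QUADRANTS",
    "differential_table",
    "quadrant_classify",
    "rbp_set_shift",
]

QUADRANTS = (
    "high_protein_normal_rna",
    "low_protein_normal_rna",
    "concordant_up",
    "concordant_down",
    "background",
)


def differential_table(
    abundance_a: pd.DataFrame,
    abundance_b: pd.DataFrame,
    log_transform: bool = True,
) -> pd.DataFrame:
    """Per-gene log2 fold change (B vs A), Welch p and BH q.

    Inputs are gene x replicate abundance tables indexed by gene id.
    With ``log_transform`` the test and the fold change are computed on
    log2 abundances (requires strictly positive values); otherwise the
    inputs are taken to be on a log-like additive scale already and the
    fold change is the difference of means.
    """
    if abundance_a.shape[1] < 2 or abundance_b.shape[1] < 2:
        raise ValueError("need >= 2 replicates per condition")
    common = abundance_a.index.intersection(abundance_b.index)
    dropped = (len(abundance_a) - len(common)) + (len(abundance_b) - len(common))
    if dropped:
        logger.warning("dropped %d gene rows absent from one condition", dropped)
    if len(common) == 0:
        raise ValueError("no shared genes")
    a = abundance_a.loc[common].to_numpy(dtype=float)
    b = abundance_b.loc[common].to_numpy(dtype=float)
    if log_transform:
        if np.any(a <= 0) or np.any(b <= 0):
            raise ValueError("abundances must be > 0 for log transform")
        a, b = np.log2(a), np.log2(b)
    _, _, pvals = welch_t_test_rows(b, a)
    df = pd.DataFrame(
        {
            "gene_id": common,
            "log2fc": b.mean(axis=1) - a.mean(axis=1),
            "p_value": pvals,
        }
    )
    df["q_value"] = bh_fdr(df["p_value"].to_numpy())
    return df


def quadrant_classify(
    records: pd.DataFrame,
    protein_q_max: float = 0.05,
    protein_lfc_min: float = 1.0,
    rna_lfc_max: float = 0.5,
) -> pd.DataFrame:
    """Label each gene by its protein/transcript fold-change quadrant.

    ``high_protein_normal_rna``: protein q <= ``protein_q_max``, protein
    log2FC >= ``protein_lfc_min`` and |rna log2FC| <= ``rna_lfc_max`` —
    the geometric definition of the "significantly enriched protein,
    normal transcript" region; mirrored for depletion; genes significant
    in protein with a concordant transcript change are ``concordant_*``;
    everything else is ``background``.  Requires columns protein_log2fc,
    protein_q, rna_log2fc.
    """
    if min(protein_q_max, protein_lfc_min, rna_lfc_max) <= 0:
        raise ValueError("thresholds must be positive")
    df = records.copy()
    plfc = df["protein_log2fc"].to_numpy(dtype=float)
    pq = df["protein_q"].to_numpy(dtype=float)
    rlfc = df["rna_log2fc"].to_numpy(dtype=float)
    sig_up = (pq <= protein_q_max) & (plfc >= protein_lfc_min)
    sig_dn = (pq <= protein_q_max) & (plfc <= -protein_lfc_min)
    rna_flat = np.abs(rlfc) <= rna_lfc_max
    labels = np.full(len(df), "background", dtype=object)
    labels[sig_up & rna_flat] = "high_protein_normal_rna"
    labels[sig_dn & rna_flat] = "low_protein_normal_rna"
    labels[sig_up & ~rna_flat & (rlfc > 0)] = "concordant_up"
    labels[sig_dn & ~rna_flat & (rlfc < 0)] = "concordant_down"
    df["quadrant"] = labels
    return df


def rbp_set_shift(records: pd.DataFrame) -> tuple[TestResult, dict[str, float]]:
    """Welch test of protein log2FC between RBP-flagged and other genes.

    Returns the test result (estimate = mean difference, RBP minus
    non-RBP) and a summary with the median difference and group sizes.
    Requires columns ``protein_log2fc`` and boolean ``is_rbp``.
    """
    is_rbp = records["is_rbp"].astype(bool).to_numpy()
    rbp = records.loc[is_rbp, "protein_log2fc"].to_numpy(dtype=float)
    non = records.loc[~is_rbp, "protein_log2fc"].to_numpy(dtype=float)
    if rbp.size < 3 or non.size < 3:
        raise ValueError("need >= 3 RBP and >= 3 non-RBP records")
    res = welch_t_test(rbp, non)
    summary = {
        "mean_shift": float(rbp.mean() - non.mean()),
        "median_shift": float(np.median(rbp) - np.median(non)),
        "n_rbp": int(rbp.size),
        "n_non_rbp": int(non.size),
    }
    return res, summary
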