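"""Paired protein/transcript abundance tables with designated subsets.

Two designed, disjoint gene subsets are planted on top of a null
background: a "retained protein" subset whose protein log2 fold change
is centered at ``protein_effect`` while its transcript fold change stays
at zero, and an RBP-flagged subset whose protein fold change is shifted
by ``rbp_shift`` (negative values emulate the aging-associated depletion
of RNA-binding proteins).  Replicate abundances are log-normal around
each gene's baseline.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["simulate_expression_pairs"]


def simulate_expression_pairs(
    n_genes: int = 2000,
    frac_high_protein_normal_rna: float = 0.1,
    protein_effect: float = 1.5,
    n_replicates: int = 3,
    noise_sd: float = 0.5,
    rbp_fraction: float = 0.2,
    rbp_shift: float = -1.0,
    seed: int = 0,
) -> dict:
    """Generate replicate abundance tables and ground truth.

    Returns a dict with linear-scale gene x replicate DataFrames
    ``protein_a``, ``protein_b``, ``rna_a``, ``rna_b`` and a ``truth``
    DataFrame (gene_id, is_high_protein, is_rbp, true protein/rna log2fc).
    """
    if not (0.0 <= frac_high_protein_normal_rna <= 1.0):
        raise ValueError("frac_high_protein_normal_rna must be in [0,1]")
    if not (0.0 <= rbp_fraction <= 1.0):
        raise ValueError("rbp_fraction must be in [0,1]")
    if frac_high_protein_normal_rna + rbp_fraction > 1.0:
        raise ValueError("designated subsets must fit disjointly in the gene set")
    if n_replicates < 2:
        raise ValueError("n_replicates must be >= 2")
    if n_genes < 10:
        raise ValueError("n_genes must be >= 10")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    genes = [f"g{i}" for i in range(n_genes)]
    n_high = int(round(frac_high_protein_normal_rna * n_genes))
    n_rbp = int(round(rbp_fraction * n_genes))
    is_high = np.zeros(n_genes, dtype=bool)
    is_rbp = np.zeros(n_genes, dtype=bool)
    is_high[:n_high] = True
    is_rbp[n_high : n_high + n_rbp] = True

    protein_fc = np.where(is_high, protein_effect, 0.0) + np.where(
        is_rbp, rbp_shift, 0.0
    )
    rna_fc = np.zeros(n_genes)

    base_protein = rng.normal(10.0, 1.0, n_genes)
    base_rna = rng.normal(8.0, 1.0, n_genes)

    def replicate_table(base: np.ndarray, shift: np.ndarray, tag: str) -> pd.DataFrame:
        log2_vals = (
            base[:, None]
            + shift[:, None]
            + rng.normal(0.0, noise_sd, (n_genes, n_replicates))
        )
        return pd.DataFrame(
            np.exp2(log2_vals),
            index=pd.Index(genes, name="gene_id"),
            columns=[f"{tag}{r + 1}" for r in range(n_replicates)],
        )

    out = {
        "protein_a": replicate_table(base_protein, np.zeros(n_genes), "A"),
        "protein_b": replicate_table(base_protein, protein_fc, "B"),
        "rna_a": replicate_table(base_rna, np.zeros(n_genes), "A"),
        "rna_b": replicate_table(base_rna, rna_fc, "B"),
        "truth": pd.DataFrame(
            {
                "gene_id": genes,
                "is_high_protein": is_high,
                "is_rbp": is_rbp,
                "true_protein_log2fc": protein_fc,
                "true_rna_log2fc": rna_fc,
            }
        ),
    }
    return out
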