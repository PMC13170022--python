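"""Label propagation, hypergeometric term enrichment and size ratios.

Essential and environment-response labels are carried from curated
reference gene lists onto contigs via their best reference-database hit.
Over-representation of GO/KEGG terms in a contig subset against a
background universe uses the upper-tail hypergeometric probability with
Benjamini-Hochberg (default) or Bonferroni correction; terms with
corrected p below alpha are significant.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


def propagate_labels(
    best_ref_hits: pd.DataFrame, label_lists: Mapping[str, Iterable[str]]
) -> pd.DataFrame:
    """Label contigs whose best reference subject is in a reference list.

    `best_ref_hits` holds one best hit per contig (qseqid, sseqid, ...);
    `label_lists` maps label name (e.g. "essential", "environmental") to
    reference gene identifiers. A contig may carry several labels when
    the lists overlap. Returns contig_id, subject_id and one boolean
    column per label.
    """
    sets = {name: set(ids) for name, ids in label_lists.items()}
    out = pd.DataFrame(
        {
            "contig_id": best_ref_hits["qseqid"].astype(str),
            "subject_id": best_ref_hits["sseqid"].astype(str),
        }
    )
    for name, ids in sets.items():
        out[name] = out["subject_id"].isin(ids)
    return out


def term_sizes(
    assignments: pd.DataFrame, subset: Iterable[str], background: Iterable[str]
) -> pd.DataFrame:
    """Per-term (k, n, K, N) counts for enrichment.

    `assignments` has columns (id, term_id), one row per membership.
    k = term members in the subset, n = subset size, K = term members in
    the background, N = background size. Terms present in the background
    but absent from the subset get k = 0.
    """
    subset_set, background_set = set(subset), set(background)
    if not subset_set <= background_set:
        raise ValueError("subset must be contained in the background")
    in_bg = assignments.loc[assignments["id"].isin(background_set)]
    big_k = in_bg.groupby("term_id")["id"].nunique()
    in_sub = in_bg.loc[in_bg["id"].isin(subset_set)]
    small_k = in_sub.groupby("term_id")["id"].nunique()
    out = pd.DataFrame({"term_id": big_k.index, "K": big_k.values})
    out["k"] = out["term_id"].map(small_k).fillna(0).astype(int)
    out["n"] = len(subset_set)
    out["N"] = len(background_set)
    return out[["term_id", "k", "n", "K", "N"]].sort_values("term_id").reset_index(
        drop=True
    )


def hypergeom_p(k: int, n: int, K: int, N: int) -> float:
    """Upper-tail hypergeometric probability P(X >= k).

    X counts term members among n draws without replacement from a
    universe of N ids of which K carry the term.
    """
    if not (0 <= k <= min(n, K) and n <= N and K <= N and k >= 0):
        raise ValueError(f"inconsistent counts k={k}, n={n}, K={K}, N={N}")
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, clipped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def enrich(
    sizes: pd.DataFrame, method: str = "fdr_bh"
) -> pd.DataFrame:
    """Attach raw and corrected p-values to a term-size table.

    method: "fdr_bh" (default) or "bonferroni".
    """
    out = sizes.copy()
    out["p"] = [
        hypergeom_p(r.k, r.n, r.K, r.N) for r in out.itertuples()
    ]
    if method == "fdr_bh":
        out["p_adj"] = bh_adjust(out["p"].to_numpy())
    elif method == "bonferroni":
        out["p_adj"] = np.clip(out["p"].to_numpy() * len(out), 0, 1)
    else:
        raise ValueError(f"unknown correction method {method!r}")
    return out


def size_ratio(count_a: float, count_b: float, decimals: int = 2) -> float | None:
    """count_a / count_b rounded half-to-even; None when count_b is zero."""
    if count_a < 0 or count_b < 0:
        raise ValueError("counts must be non-negative")
    if count_b == 0:
        return None
    return round(count_a / count_b, decimals)


def top_terms(
    results: pd.DataFrame, top_n: int, alpha: float = 0.05
) -> pd.DataFrame:
    """Significant terms (p_adj strictly below alpha), ordered by raw p
    then term_id, truncated to `top_n`."""
    sig = results.loc[results["p_adj"] < alpha]
    return (
        sig.sort_values(["p", "term_id"], kind="mergesort")
        .head(top_n)
        .reset_index(drop=True)
    )
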