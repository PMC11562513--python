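"""TCR-beta clonotype tables and vaccination-associated expansion testing.

A clonotype is a CDR3-beta amino-acid sequence; tables hold counts and
frequencies per patient / timepoint / stimulation condition.  Expansion of a
clonotype from pre- to post-vaccination is tested with the one-sided exact
2x2 test (hypergeometric tail with fixed margins, i.e. Fisher's exact test
for enrichment), Benjamini-Hochberg corrected across the clonotypes of a
repertoire pair, with an additional pseudocounted fold-change floor so that
low-depth flickers are not called expanded.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .config import ExpansionConfig


def build_table(counts: Mapping[str, int] | pd.DataFrame) -> pd.DataFrame:
    """Clonotype table (cdr3b, count, frequency) from raw counts; zero-count
    rows are dropped and frequencies sum to 1."""
    if isinstance(counts, pd.DataFrame):
        df = counts[["cdr3b", "count"]].copy()
    else:
        df = pd.DataFrame({"cdr3b": list(counts), "count": list(counts.values())})
    if (df["count"] < 0).any() or (df["count"] % 1 != 0).any():
        raise ValueError("clonotype counts must be non-negative integers")
    df = (df.groupby("cdr3b", as_index=False, sort=True)["count"].sum())
    df = df[df["count"] > 0].reset_index(drop=True)
    total = df["count"].sum()
    if total == 0:
        raise ValueError("clonotype table is empty")
    df["frequency"] = df["count"] / total
    return df


def exact_enrichment_p(c_pre: np.ndarray, n_pre: int,
                       c_post: np.ndarray, n_post: int) -> np.ndarray:
    """One-sided exact p-value that the post frequency exceeds the pre
    frequency: upper hypergeometric tail of the 2x2 table
    [[c_post, n_post-c_post], [c_pre, n_pre-c_pre]] with fixed margins."""
    c_pre = np.asarray(c_pre, dtype=np.int64)
    c_post = np.asarray(c_post, dtype=np.int64)
    return stats.hypergeom.sf(c_post - 1, n_pre + n_post, c_pre + c_post, n_post)


def test_expansion(pre_table: pd.DataFrame, post_table: pd.DataFrame,
                   config: ExpansionConfig | None = None) -> pd.DataFrame:
    """Per-clonotype expansion results for one patient/condition pair.

    fold = pseudocounted frequency ratio post/pre; p from the one-sided exact
    test; q Benjamini-Hochberg across the union of clonotypes; expanded iff
    q < alpha AND fold >= min_fold AND freq_post > freq_pre."""
    cfg = config or ExpansionConfig()
    if len(pre_table) == 0 or len(post_table) == 0:
        raise ValueError("both clonotype tables must be non-empty")
    pre = pre_table.set_index("cdr3b")["count"]
    post = post_table.set_index("cdr3b")["count"]
    union = sorted(set(pre.index) | set(post.index))
    c_pre = pre.reindex(union, fill_value=0).to_numpy(dtype=np.int64)
    c_post = post.reindex(union, fill_value=0).to_numpy(dtype=np.int64)
    n_pre, n_post = int(c_pre.sum()), int(c_post.sum())
    ps = cfg.pseudocount
    freq_pre = c_pre / n_pre
    freq_post = c_post / n_post
    fold = ((c_post + ps) / (n_post + ps)) / ((c_pre + ps) / (n_pre + ps))
    p = exact_enrichment_p(c_pre, n_pre, c_post, n_post)
    q = multipletests(p, method="fdr_bh")[1]
    return pd.DataFrame({
        "cdr3b": union, "count_pre": c_pre, "count_post": c_post,
        "freq_pre": freq_pre, "freq_post": freq_post, "fold_change": fold,
        "p_value": p, "q_value": q,
        "expanded": (q < cfg.alpha) & (fold >= cfg.min_fold) & (freq_post > freq_pre),
    })


def dominant_clonotype(table: pd.DataFrame) -> tuple[str, float]:
    """Highest-frequency clonotype; ties broken lexicographically."""
    df = table.sort_values(["count", "cdr3b"], ascending=[False, True],
                           kind="mergesort")
    row = df.iloc[0]
    return str(row["cdr3b"]), float(row["count"] / table["count"].sum())


def classify_repertoire_response(expansion: pd.DataFrame) -> str:
    """none (0 expanded clonotypes), monoclonal (1), or oligoclonal (>= 2)."""
    n = int(expansion["expanded"].sum())
    return "none" if n == 0 else ("monoclonal" if n == 1 else "oligoclonal")


@dataclass(frozen=True)
class RepertoireSummary:
    patient: str
    condition: str
    n_expanded: int
    response_class: str
    dominant_cdr3b: str
    dominant_freq_post: float


def summarize_repertoires(clonotypes: pd.DataFrame,
                          config: ExpansionConfig | None = None,
                          ) -> tuple[pd.DataFrame, list[RepertoireSummary]]:
    """Run the expansion test for every (patient, condition) with both
    timepoints in a tidy clonotype table (patient, condition, timepoint,
    cdr3b, count).  Returns the concatenated expansion table and per-pair
    summaries."""
    results, summaries = [], []
    for (patient, condition), group in clonotypes.groupby(["patient", "condition"],
                                                          sort=True):
        pre = group[group["timepoint"] == "pre"]
        post = group[group["timepoint"] == "post"]
        if len(pre) == 0 or len(post) == 0:
            continue
        res = test_expansion(build_table(pre), build_table(post), config)
        res.insert(0, "patient", patient)
        res.insert(1, "condition", condition)
        results.append(res)
        dom, freq = dominant_clonotype(build_table(post))
        summaries.append(RepertoireSummary(
            patient, condition, int(res["expanded"].sum()),
            classify_repertoire_response(res), dom, freq))
    table = (pd.concat(results, ignore_index=True) if results
             else pd.DataFrame())
    return table, summaries
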