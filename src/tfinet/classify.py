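"""TBP family-insensitive (TFI) transcript classification and clustering.

A transcript is TFI when it is (1) not affected by knockdown of any of the
three TBP-family initiation factors and (2) either developmentally induced
between blastula and gastrula stages or sensitive to the RNA polymerase II
inhibitor alpha-amanitin. "Affected" is a composite: a replicate-consistent
signed-rank change call together with a log2 fold-change beyond the gate.

Clustering of per-condition expression ratios uses k-means under Pearson
correlation distance, the standard view for grouping response profiles
irrespective of amplitude.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import stats
from .simulate import design_samples
from .stats import ChangeCall, Thresholds, consistent_call

KD_CONDITIONS = ("tbp_as", "tlf_as", "tbp2_as")


@dataclass(frozen=True)
class ClassificationRuleSet:
    """Log2 gates and the per-comparison alpha for the compound TFI rule.

    ``unaffected_requires_fold_gate`` switches the "not affected" criterion
    between the composite (consistent call AND |lfc| >= kd_lfc; default) and
    call absence alone.
    """

    dev_lfc: float = 1.5
    kd_lfc: float = 1.5
    alpha: float = 0.05
    amanitin_lfc: float = 1.5
    floor: float = 8.0
    unaffected_requires_fold_gate: bool = True

    def __post_init__(self):
        for name in ("dev_lfc", "kd_lfc", "amanitin_lfc"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def thresholds(self) -> Thresholds:
        return Thresholds(alpha=self.alpha, lfc=self.dev_lfc, floor=self.floor)


def _replicate_calls(probe_values: pd.DataFrame, probe_map: pd.Series,
                     design: pd.DataFrame, cell_a: tuple[str, str],
                     cell_b: tuple[str, str], rules: ClassificationRuleSet
                     ) -> pd.DataFrame:
    """Matched-replicate change calls for sample cell B vs cell A.

    Replicate pairing is positional (rep 1 vs rep 1, rep 2 vs rep 2, ...).
    Returns one row per transcript with per-replicate calls and the mean
    log2 ratio across replicate comparisons.
    """
    a_samples = design_samples(design, *cell_a)
    b_samples = design_samples(design, *cell_b)
    n_rep = min(len(a_samples), len(b_samples))
    if n_rep < 2:
        raise ValueError("need >=2 replicate comparisons")
    th = rules.thresholds()
    order = probe_map.reindex(probe_values.index)
    rows = {}
    grouped = probe_values.groupby(order, sort=True)
    for transcript, block in grouped:
        calls = []
        ratios = []
        for r in range(n_rep):
            c = stats.change_call(block[a_samples[r]].to_numpy(),
                                  block[b_samples[r]].to_numpy(), th,
                                  transcript_id=str(transcript),
                                  comparison=f"rep{r + 1}")
            calls.append(c.call)
            ratios.append(c.log2_ratio)
        rows[transcript] = {
            "consistent": consistent_call(calls),
            "mean_log2_ratio": float(np.mean(ratios)),
            **{f"call_rep{r + 1}": calls[r] for r in range(n_rep)},
        }
    return pd.DataFrame.from_dict(rows, orient="index").sort_index()


def developmentally_induced(probe_values, probe_map, design,
                            rules: ClassificationRuleSet | None = None
                            ) -> set[str]:
    """Transcripts consistently Increased from stage 7 to 10.5 with
    mean log2 ratio above the developmental gate."""
    rules = rules or ClassificationRuleSet()
    calls = _replicate_calls(probe_values, probe_map, design,
                             ("st7", "control"), ("st10.5", "control"), rules)
    hit = (calls["consistent"] == stats.INCREASE) & \
          (calls["mean_log2_ratio"] > rules.dev_lfc)
    return set(calls.index[hit])


def knockdown_dependent(probe_values, probe_map, design, condition: str,
                        rules: ClassificationRuleSet | None = None
                        ) -> set[str]:
    """Transcripts consistently Decreased under one factor knockdown with
    mean log2 ratio below -kd_lfc."""
    rules = rules or ClassificationRuleSet()
    calls = _replicate_calls(probe_values, probe_map, design,
                             ("st10.5", "control"), ("st10.5", condition),
                             rules)
    hit = (calls["consistent"] == stats.DECREASE) & \
          (calls["mean_log2_ratio"] < -rules.kd_lfc)
    return set(calls.index[hit])


def unaffected_by_all(probe_values, probe_map, design,
                      rules: ClassificationRuleSet | None = None
                      ) -> set[str]:
    """Transcripts not "affected" by any of the three single knockdowns.

    Affected = consistent call in either direction AND (optionally, the
    default) |mean log2 ratio| >= kd_lfc.
    """
    rules = rules or ClassificationRuleSet()
    affected: set[str] = set()
    universe: set[str] = set()
    for cond in KD_CONDITIONS:
        calls = _replicate_calls(probe_values, probe_map, design,
                                 ("st10.5", "control"), ("st10.5", cond),
                                 rules)
        universe |= set(calls.index)
        has_call = calls["consistent"].isin([stats.INCREASE, stats.DECREASE])
        if rules.unaffected_requires_fold_gate:
            hit = has_call & (calls["mean_log2_ratio"].abs() >= rules.kd_lfc)
        else:
            hit = has_call
        affected |= set(calls.index[hit])
    return universe - affected


def amanitin_sensitive(probe_values, probe_map, design,
                       rules: ClassificationRuleSet | None = None
                       ) -> set[str]:
    """Transcripts consistently Decreased by alpha-amanitin beyond the gate
    — the operational certificate of active zygotic transcription."""
    rules = rules or ClassificationRuleSet()
    calls = _replicate_calls(probe_values, probe_map, design,
                             ("st10.5", "control"), ("st10.5", "amanitin"),
                             rules)
    hit = (calls["consistent"] == stats.DECREASE) & \
          (calls["mean_log2_ratio"] <= -rules.amanitin_lfc)
    return set(calls.index[hit])


def tfi_set(probe_values, probe_map, design,
            rules: ClassificationRuleSet | None = None) -> pd.DataFrame:
    """Full labeling table with the compound TFI flag.

    tfi = unaffected_by_all AND (developmentally induced OR
    alpha-amanitin sensitive).
    """
    rules = rules or ClassificationRuleSet()
    induced = developmentally_induced(probe_values, probe_map, design, rules)
    dep = {cond: knockdown_dependent(probe_values, probe_map, design, cond,
                                     rules) for cond in KD_CONDITIONS}
    unaffected = unaffected_by_all(probe_values, probe_map, design, rules)
    ama = amanitin_sensitive(probe_values, probe_map, design, rules)
    transcripts = sorted(set(probe_map))
    df = pd.DataFrame(index=pd.Index(transcripts, name="transcript_id"))
    df["induced"] = [t in induced for t in transcripts]
    df["tbp_dep"] = [t in dep["tbp_as"] for t in transcripts]
    df["tlf_dep"] = [t in dep["tlf_as"] for t in transcripts]
    df["tbp2_dep"] = [t in dep["tbp2_as"] for t in transcripts]
    df["amanitin_sensitive"] = [t in ama for t in transcripts]
    df["unaffected_all"] = [t in unaffected for t in transcripts]
    df["tfi"] = df["unaffected_all"] & (df["induced"] | df["amanitin_sensitive"])
    return df


def ratio_matrix(probe_values, probe_map, design,
                 rules: ClassificationRuleSet | None = None
                 ) -> pd.DataFrame:
    """Per-replicate condition/control log2 ratio profiles per transcript.

    Columns: (tbp_as, tlf_as, tbp2_as, amanitin) vs stage-10.5 control and
    stage 10.5 vs stage 7, one column per replicate — the feature space for
    ratio clustering.
    """
    rules = rules or ClassificationRuleSet()
    summarized, _ = stats.summarize_probes(probe_values, probe_map,
                                           floor=rules.floor)
    cols = {}
    ctrl = design_samples(design, "st10.5", "control")
    st7 = design_samples(design, "st7", "control")
    for cond in (*KD_CONDITIONS, "amanitin"):
        for r, sample in enumerate(design_samples(design, "st10.5", cond)):
            cols[f"{cond}_r{r + 1}"] = summarized[sample] - summarized[ctrl[r]]
    for r, sample in enumerate(ctrl):
        cols[f"st10.5_vs_st7_r{r + 1}"] = summarized[sample] - summarized[st7[r]]
    return pd.DataFrame(cols)


def kmeans_ratio_clusters(ratios: pd.DataFrame, k: int = 8, seed: int = 0,
                          n_restarts: int = 5, max_iter: int = 100
                          ) -> tuple[pd.Series, np.ndarray, list[float]]:
    """Lloyd k-means under Pearson correlation distance.

    Rows are standardized (zero mean, unit variance) so that
    1 - corr(x, c) coincides with cosine distance and the mean-of-members
    centroid update is the exact minimizer — the objective is therefore
    non-increasing. Zero-variance rows cannot carry a correlation; they are
    assigned to cluster 0 and flagged via the returned assignment's name.

    Returns (assignment Series, centroids array (k x m), objective history
    of the best restart).
    """
    X = ratios.to_numpy(dtype=float)
    n, m = X.shape
    if k < 1 or k > n:
        raise ValueError("k must be in [1, n_rows]")
    sd = X.std(axis=1)
    degenerate = sd == 0
    Z = np.zeros_like(X)
    ok = ~degenerate
    Z[ok] = (X[ok] - X[ok].mean(axis=1, keepdims=True)) / sd[ok, None]

    def corr_dist(A, C):
        # rows of A are standardized; standardize centroids on the fly
        Cc = C - C.mean(axis=1, keepdims=True)
        norm = np.linalg.norm(Cc, axis=1)
        norm[norm == 0] = 1.0
        Cu = Cc / norm[:, None]
        return 1.0 - (A @ Cu.T) / np.sqrt(m)

    rng = np.random.default_rng(seed)
    best = None
    rows_ok = np.nonzero(ok)[0]
    for _ in range(max(1, n_restarts)):
        init = rng.choice(rows_ok if rows_ok.size >= k else np.arange(n),
                          size=k, replace=False)
        C = Z[init].copy()
        labels = np.zeros(n, dtype=int)
        history: list[float] = []
        for _it in range(max_iter):
            D = corr_dist(Z, C)
            new_labels = D.argmin(axis=1)
            new_labels[degenerate] = 0
            obj = float(D[np.arange(n), new_labels][ok].sum())
            history.append(obj)
            for j in range(k):
                members = Z[(new_labels == j) & ok]
                if len(members):
                    C[j] = members.mean(axis=0)
                else:  # re-seed an empty cluster from the farthest point
                    far = int(D.min(axis=1).argmax())
                    C[j] = Z[far]
            if (new_labels == labels).all() and _it > 0:
                labels = new_labels
                break
            labels = new_labels
        if best is None or history[-1] < best[2][-1]:
            best = (labels.copy(), C.copy(), history)
    labels, C, history = best
    assignment = pd.Series(labels, index=ratios.index, name="cluster")
    assignment.attrs["degenerate_rows"] = list(ratios.index[degenerate])
    return assignment, C, history
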