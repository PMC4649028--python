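"""Alpha diversity, rarefaction, per-OTU group tests, and PerMANOVA.

Shannon entropy uses the natural log.  Rarefaction is the analytic
hypergeometric expectation (no Monte Carlo), so curves are deterministic and
their endpoint equals observed richness exactly.  Per-OTU differences across
design groups use one-way ANOVA with Tukey HSD post-hocs and a Bonferroni
family across OTUs.  PerMANOVA follows Anderson's permutation pseudo-F on
Euclidean distances, here of Hellinger-transformed abundances.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .tables_io import CountTable, SampleMetadata


def shannon_index(counts) -> float:
    """Shannon diversity H' = -sum p_i ln p_i over non-zero proportions."""
    arr = np.asarray(counts, dtype=float)
    if (arr < 0).any():
        raise ValueError("negative counts")
    total = arr.sum()
    if total == 0:
        raise ValueError("all-zero sample has no Shannon index")
    p = arr[arr > 0] / total
    return float(-(p * np.log(p)).sum())


def richness(counts) -> int:
    """Observed number of OTUs with at least one read."""
    return int((np.asarray(counts) > 0).sum())


def rarefaction_curve(counts, depths) -> list[tuple[int, float]]:
    """Expected richness at each subsampling depth, analytically.

    E[S_d] = sum_o [1 - C(N - N_o, d) / C(N, d)] where N is the sample sum
    and N_o the reads of OTU o; evaluated with log-gamma for stability.
    """
    arr = np.asarray(counts, dtype=np.int64)
    arr = arr[arr > 0]
    total = int(arr.sum())
    out = []
    for d in depths:
        d = int(d)
        if d > total:
            raise ValueError(f"depth {d} exceeds sample sum {total}")
        # log C(N - N_o, d) - log C(N, d); C(n, d) = 0 when n < d
        with np.errstate(invalid="ignore"):
            log_miss = (
                gammaln(total - arr + 1)
                - gammaln(d + 1)
                - gammaln(total - arr - d + 1)
                - (gammaln(total + 1) - gammaln(d + 1) - gammaln(total - d + 1))
            )
        p_miss = np.where(total - arr < d, 0.0, np.exp(log_miss))
        out.append((d, float((1.0 - p_miss).sum())))
    return out


@dataclass
class DiversityResult:
    """Per-sample richness, Shannon index, and rarefaction curve."""

    sample_id: str
    richness: int
    shannon: float
    rarefaction: list[tuple[int, float]] = field(default_factory=list)


def sample_diversity(
    table: CountTable, rarefaction_points: int = 10
) -> list[DiversityResult]:
    """Richness, Shannon and an evenly spaced rarefaction curve per sample."""
    results = []
    for sample in table.sample_ids:
        col = table.counts[sample].to_numpy()
        total = int(col.sum())
        depths = np.unique(
            np.linspace(1, total, rarefaction_points, dtype=np.int64)
        )
        results.append(
            DiversityResult(
                sample_id=sample,
                richness=richness(col),
                shannon=shannon_index(col),
                rarefaction=rarefaction_curve(col, depths),
            )
        )
    return results


# ---------------------------------------------------------------------------
# per-OTU group tests
# ---------------------------------------------------------------------------


@dataclass
class GroupTestResult:
    otu_id: str
    levels: list[str]
    f_stat: float
    p_raw: float
    p_bonferroni: float
    tukey_pairs: dict[tuple[str, str], float]
    letters: dict[str, str]
    degenerate: bool = False


def _compact_letters(
    levels: list[str],
    means: dict[str, float],
    tukey_p: dict[tuple[str, str], float],
    alpha: float,
) -> dict[str, str]:
    """Greedy compact-letter display consistent with the Tukey pairs."""

    def differs(a: str, b: str) -> bool:
        return tukey_p.get((a, b), tukey_p.get((b, a), 1.0)) < alpha

    ordered = sorted(levels, key=lambda g: -means[g])
    groups: list[set[str]] = []  # letter groups: mutually non-significant sets
    for g in ordered:
        placed = False
        for s in groups:
            if all(not differs(g, other) for other in s):
                s.add(g)
                placed = True
        if not placed:
            groups.append({g})
    letters = {g: "" for g in levels}
    for s, letter in zip(groups, "abcdefghijklmnopqrstuvwxyz"):
        for g in s:
            letters[g] += letter
    return {g: "".join(sorted(v)) for g, v in letters.items()}


def per_otu_anova(
    table: CountTable,
    meta: SampleMetadata,
    factor: str = "compartment",
    alpha: float = 0.05,
) -> list[GroupTestResult]:
    """One-way ANOVA + Tukey HSD per OTU, Bonferroni-adjusted across OTUs.

    OTUs whose groups all have zero variance and identical means are flagged
    degenerate (the F statistic is undefined); groups with fewer than two
    replicates cause the OTU to be skipped with a warning.
    """
    if factor not in meta.table.columns:
        raise ValueError(f"unknown factor {factor!r}")
    labels = meta.table.loc[table.sample_ids, factor].astype(str)
    levels = sorted(labels.unique())
    if len(levels) < 2:
        raise ValueError("ANOVA requires at least two groups")
    if (labels.value_counts() < 2).any():
        small = labels.value_counts()
        warnings.warn(
            f"groups with <2 replicates skipped: "
            f"{list(small.index[small < 2])}",
            stacklevel=2,
        )
        keep = labels.isin(small.index[small >= 2])
        labels = labels[keep]
        levels = sorted(labels.unique())
    results = []
    n_tests = len(table.otu_ids)
    for otu in table.otu_ids:
        values = table.counts.loc[otu, labels.index].to_numpy(dtype=float)
        groups = [values[(labels == lv).to_numpy()] for lv in levels]
        means = {lv: float(np.mean(g)) for lv, g in zip(levels, groups)}
        if all(np.ptp(g) == 0 for g in groups) and len(set(means.values())) == 1:
            results.append(
                GroupTestResult(
                    otu, levels, np.nan, np.nan, np.nan, {}, {}, degenerate=True
                )
            )
            continue
        f_stat, p_raw = stats.f_oneway(*groups)
        tukey = pairwise_tukeyhsd(values, labels.to_numpy(), alpha=alpha)
        pair_p = {
            (str(a), str(b)): float(p)
            for (a, b), p in zip(
                [(r[0], r[1]) for r in tukey.summary().data[1:]],
                tukey.pvalues,
            )
        }
        letters = _compact_letters(levels, means, pair_p, alpha)
        results.append(
            GroupTestResult(
                otu,
                levels,
                float(f_stat),
                float(p_raw),
                min(1.0, float(p_raw) * n_tests),
                pair_p,
                letters,
            )
        )
    return results


def group_tests_to_frame(results: list[GroupTestResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        rows.append(
            {
                "otu_id": r.otu_id,
                "F": r.f_stat,
                "p_raw": r.p_raw,
                "p_bonferroni": r.p_bonferroni,
                "tukey_pairs": ";".join(
                    f"{a}-{b}:{p:.4g}" for (a, b), p in sorted(r.tukey_pairs.items())
                ),
                "letters": ";".join(f"{g}:{v}" for g, v in sorted(r.letters.items())),
                "degenerate": r.degenerate,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# PerMANOVA
# ---------------------------------------------------------------------------


def permanova(
    hellinger: pd.DataFrame,
    meta: SampleMetadata,
    factor: str = "compartment",
    n_perm: int = 999,
    seed: int = 0,
) -> tuple[float, float]:
    """Permutation MANOVA pseudo-F on Euclidean distances of Hellinger data.

    ``hellinger`` is OTU rows x sample columns (the output of
    :func:`soilnet.preprocess.hellinger_transform`).  Labels are permuted
    freely (no strata); p = (1 + #{F* >= F}) / (1 + n_perm).
    """
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    samples = list(hellinger.columns)
    labels = meta.table.loc[samples, factor].astype(str).to_numpy()
    levels = np.unique(labels)
    if len(levels) < 2:
        raise ValueError("PerMANOVA requires at least two groups")
    x = hellinger.to_numpy(dtype=float).T  # samples x features
    d2 = (
        np.sum(x**2, axis=1)[:, None]
        + np.sum(x**2, axis=1)[None, :]
        - 2 * x @ x.T
    )
    np.fill_diagonal(d2, 0.0)
    d2 = np.clip(d2, 0.0, None)
    n = len(samples)
    a = len(levels)

    def pseudo_f(lab: np.ndarray) -> float:
        ss_total = d2[np.triu_indices(n, 1)].sum() / n
        ss_within = 0.0
        for lv in levels:
            idx = np.flatnonzero(lab == lv)
            if len(idx) < 2:
                continue
            sub = d2[np.ix_(idx, idx)]
            ss_within += sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
        ss_among = ss_total - ss_within
        return (ss_among / (a - 1)) / (ss_within / (n - a))

    observed = pseudo_f(labels)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        if pseudo_f(rng.permutation(labels)) >= observed:
            exceed += 1
    return float(observed), (1 + exceed) / (1 + n_perm)
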