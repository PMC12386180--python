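"""Supervised admixture estimation against four reference clusters.

The monitoring question is how much Columbia Basin (CB) ancestry each
rabbit retains given four predefined source lineages.  With cluster allele
frequencies estimated from known-origin individuals and held fixed, the
admixture vector q of an individual is the maximum-likelihood mixture
weight of its allele copies:

    L(q) = prod over allele copies j of  sum_k q_k * f_k(allele_j)

maximised by EM over the probability simplex.  An individual "contains CB
ancestry" when q_CB >= 0.05, the threshold below which known non-CB
animals' CB assignments fall.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .synthetic import CLUSTER_NAMES


@dataclass
class ReferencePanel:
    """Per-cluster, per-locus smoothed allele frequencies."""

    cluster_names: tuple[str, ...]
    freqs: dict[str, dict[str, dict[int, float]]]  # cluster -> locus -> allele -> f
    pseudocount: float
    n_individuals: dict[str, int]

    def loci(self) -> list[str]:
        first = self.freqs[self.cluster_names[0]]
        return sorted(first)


def build_reference_panel(
    genotypes: dict[str, dict[str, tuple[int, int]]],
    labels: dict[str, str],
    pseudocount: float = 0.5,
    cluster_names: tuple[str, ...] = CLUSTER_NAMES,
) -> ReferencePanel:
    """Estimate cluster allele frequencies from known-origin individuals.

    Additive smoothing over the union of alleles observed anywhere at the
    locus: f = (count + c) / (copies + c * n_alleles), so every observed
    allele has nonzero frequency in every cluster and no genotype has zero
    likelihood.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    members: dict[str, list[str]] = {c: [] for c in cluster_names}
    for ind, cluster in labels.items():
        if cluster not in members:
            raise ValueError(f"unknown cluster label {cluster!r}")
        if ind in genotypes:
            members[cluster].append(ind)
    empty = [c for c, m in members.items() if not m]
    if empty:
        raise ValueError(f"clusters without reference individuals: {empty}")
    # global allele universe per locus
    universe: dict[str, set[int]] = {}
    for geno in genotypes.values():
        for locus, pair in geno.items():
            universe.setdefault(locus, set()).update(pair)
    freqs: dict[str, dict[str, dict[int, float]]] = {}
    for cluster, inds in members.items():
        freqs[cluster] = {}
        for locus, alleles in universe.items():
            counts = dict.fromkeys(sorted(alleles), 0)
            copies = 0
            for ind in inds:
                pair = genotypes[ind].get(locus)
                if pair is None:
                    continue
                for a in pair:
                    counts[a] = counts.get(a, 0) + 1
                    copies += 1
            denom = copies + pseudocount * len(counts)
            freqs[cluster][locus] = {
                a: (n + pseudocount) / denom for a, n in counts.items()
            }
    return ReferencePanel(
        cluster_names=tuple(cluster_names),
        freqs=freqs,
        pseudocount=pseudocount,
        n_individuals={c: len(m) for c, m in members.items()},
    )


def panel_from_clusters(
    clusters, loci, floor: float = 1e-4
) -> ReferencePanel:
    """Wrap generating-truth cluster frequencies as a reference panel
    (useful when the simulator's frequencies are taken as known).

    Every ladder allele is floored to a small positive frequency and the
    locus renormalised, so genotypes carrying rare or drifted alleles keep
    nonzero likelihood, mirroring the smoothing contract of estimated
    panels.
    """
    freqs = {}
    for c in clusters:
        freqs[c.name] = {}
        for l in loci:
            if l.is_sex_linked:
                continue
            table = {a: f + floor for a, f in c.freqs[l.name].items()}
            total = sum(table.values())
            freqs[c.name][l.name] = {a: f / total for a, f in table.items()}
    return ReferencePanel(
        cluster_names=tuple(c.name for c in clusters),
        freqs=freqs,
        pseudocount=floor,
        n_individuals={c.name: 0 for c in clusters},
    )


@dataclass
class AncestryEstimate:
    individual_id: str
    q: np.ndarray
    loglik: float
    n_iters: int
    converged: bool

    def as_dict(self) -> dict[str, float]:
        return {
            f"q_{name}": float(v)
            for name, v in zip(CLUSTER_NAMES, self.q)
        }


def _copy_matrix(
    genotype: dict[str, tuple[int, int]],
    panel: ReferencePanel,
) -> np.ndarray:
    """F[j, k] = frequency of allele copy j in cluster k."""
    rows = []
    for locus in sorted(genotype):
        tables = [
            panel.freqs[c].get(locus) for c in panel.cluster_names
        ]
        if any(t is None for t in tables):
            continue
        for allele in genotype[locus]:
            row = [t.get(allele) for t in tables]
            if any(v is None or v <= 0 for v in row):
                raise ValueError(
                    f"allele {allele} at {locus} not covered by the panel; "
                    "rebuild the panel over the full allele universe"
                )
            rows.append(row)
    return np.array(rows, dtype=float)


def _em(
    F: np.ndarray, q0: np.ndarray, tol: float, max_iter: int
) -> tuple[np.ndarray, float, int, bool, list[float]]:
    q = q0.copy()
    ll_prev = -np.inf
    trace: list[float] = []
    for it in range(1, max_iter + 1):
        mix = F @ q
        ll = float(np.log(mix).sum())
        trace.append(ll)
        if np.isfinite(ll_prev):
            rel = abs(ll - ll_prev) / max(abs(ll_prev), 1.0)
            if rel < tol:
                return q, ll, it, True, trace
        ll_prev = ll
        resp = F * q / mix[:, None]
        q = resp.mean(axis=0)
        q = np.maximum(q, 0.0)
        q /= q.sum()
    mix = F @ q
    ll = float(np.log(mix).sum())
    trace.append(ll)
    return q, ll, max_iter, False, trace


def estimate_admixture_em(
    genotype: dict[str, tuple[int, int]],
    panel: ReferencePanel,
    tol: float = 1e-8,
    max_iter: int = 2000,
    n_starts: int = 10,
    seed: int = 0,
    individual_id: str = "",
) -> AncestryEstimate:
    """Maximum-likelihood admixture vector by EM, best of ``n_starts``.

    The first start is the uniform vector (the only symmetric point, so an
    unidentifiable flat likelihood returns 1/K per cluster); the rest are
    Dirichlet(1) draws.  The log-likelihood is non-decreasing along every
    EM path; a violation beyond numerical noise raises.
    """
    if not genotype:
        raise ValueError("individual has zero usable loci")
    F = _copy_matrix(genotype, panel)
    if F.size == 0:
        raise ValueError("no locus of this genotype is covered by the panel")
    K = len(panel.cluster_names)
    rng = np.random.default_rng(seed)
    starts = [np.full(K, 1.0 / K)]
    for _ in range(max(n_starts - 1, 0)):
        starts.append(rng.dirichlet(np.ones(K)))
    best: AncestryEstimate | None = None
    for q0 in starts:
        q, ll, iters, conv, trace = _em(F, q0, tol, max_iter)
        drops = [
            b - a for a, b in zip(trace, trace[1:]) if b - a < -1e-8
        ]
        if drops:
            raise RuntimeError(
                f"EM log-likelihood decreased by {min(drops)}"
            )
        if best is None or ll > best.loglik + 1e-12:
            best = AncestryEstimate(individual_id, q, ll, iters, conv)
    assert best is not None
    return best


def classify_cb(
    estimates: list[AncestryEstimate],
    threshold: float = 0.05,
    cb_index: int = 0,
    wild_born_ids: set[str] | None = None,
) -> dict:
    """CB-ancestry classification and cohort summaries.

    An individual contains CB ancestry iff q_CB >= threshold (inclusive).
    Returns per-individual booleans plus the cohort mean CB percentage, the
    percentage of individuals containing CB ancestry, and the same
    percentage restricted to wild-born individuals when their ids are
    given.
    """
    flags = {
        e.individual_id: bool(e.q[cb_index] >= threshold)
        for e in estimates
    }
    if estimates:
        mean_cb = float(
            np.mean([e.q[cb_index] for e in estimates]) * 100.0
        )
        pct_cb = 100.0 * sum(flags.values()) / len(flags)
    else:
        mean_cb = float("nan")
        pct_cb = float("nan")
    out = {
        "contains_cb": flags,
        "mean_cb_pct": mean_cb,
        "pct_containing_cb": pct_cb,
    }
    if wild_born_ids is not None:
        wb = [i for i in flags if i in wild_born_ids]
        out["pct_wild_born_containing_cb"] = (
            100.0 * sum(flags[i] for i in wb) / len(wb)
            if wb
            else float("nan")
        )
    return out
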