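"""Hypergeometric over-representation analysis of top-ranked proteins.

Given the top-k proteins selected by the forest and a pathway membership
map, each pathway is scored by the upper-tail hypergeometric probability
of drawing at least the observed number of its members when n proteins
are selected from a universe of N (population N, K pathway members,
n draws, k overlap):

    p = P(X >= k),  X ~ Hypergeometric(N, K, n)

The tail is accumulated in log space from scipy's log-pmf for stability
at extreme parameters.  A pmf variant (P(X = k) exactly) is provided for
replicating analyses that report point probabilities instead of tails.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import hypergeom

__all__ = [
    "PathwayMap",
    "EnrichmentResult",
    "hypergeom_tail",
    "hypergeom_pmf",
    "enrich_pathways",
    "read_gmt",
    "write_gmt",
    "benjamini_hochberg",
]


@dataclass
class PathwayMap:
    """pathway_id -> member protein ids, plus the eligible universe size N."""

    pathways: dict[str, set[str]]
    universe_size: int
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for pid, members in self.pathways.items():
            if not members:
                raise ValueError(f"pathway {pid!r} is empty")
        union = set().union(*self.pathways.values()) if self.pathways else set()
        if self.universe_size < len(union):
            raise ValueError(
                f"universe_size {self.universe_size} smaller than pathway union {len(union)}"
            )


@dataclass(frozen=True)
class EnrichmentResult:
    pathway_id: str
    pathway_size: int
    overlap: int
    overlap_proteins: frozenset
    p_value: float


def _check_params(N: int, K: int, n: int, k: int) -> None:
    if not (0 <= k <= n <= N and 0 <= K <= N):
        raise ValueError(f"inconsistent hypergeometric parameters N={N} K={K} n={n} k={k}")


def hypergeom_tail(N: int, K: int, n: int, k: int) -> float:
    """Upper tail P(X >= k) for X ~ Hypergeometric(N, K, n), log-space sum."""
    _check_params(N, K, n, k)
    if k == 0:
        return 1.0
    hi = min(K, n)
    if k > hi:
        return 0.0
    ks = np.arange(k, hi + 1)
    return float(min(1.0, np.exp(logsumexp(hypergeom.logpmf(ks, N, K, n)))))


def hypergeom_pmf(N: int, K: int, n: int, k: int) -> float:
    """Point probability P(X = k)."""
    _check_params(N, K, n, k)
    return float(hypergeom.pmf(k, N, K, n))


def enrich_pathways(
    top_proteins: Sequence[str],
    pmap: PathwayMap,
    min_overlap: int = 2,
    stat: str = "tail",
) -> list[EnrichmentResult]:
    """Score every pathway overlapping the top set; ascending p, ties by id.

    The number of draws n counts only top proteins inside the universe
    (taken as the union of pathway members when the universe is exactly
    that union, otherwise all top proteins are assumed eligible), so
    unannotated proteins cannot inflate significance.
    """
    if not top_proteins:
        raise ValueError("top protein set is empty")
    if pmap.universe_size <= 0:
        raise ValueError("empty universe")
    if stat not in ("tail", "pmf"):
        raise ValueError("stat must be 'tail' or 'pmf'")
    top = set(top_proteins)
    union = set().union(*pmap.pathways.values()) if pmap.pathways else set()
    if pmap.universe_size == len(union):
        eligible = top & union
    else:
        eligible = top  # universe extends beyond annotated proteins
    n = len(eligible)
    score = hypergeom_tail if stat == "tail" else hypergeom_pmf

    results = []
    for pid in sorted(pmap.pathways):
        members = pmap.pathways[pid]
        overlap = eligible & members
        if len(overlap) < min_overlap:
            continue
        K = min(len(members), pmap.universe_size)
        p = score(pmap.universe_size, K, n, len(overlap))
        results.append(
            EnrichmentResult(
                pathway_id=pid,
                pathway_size=len(members),
                overlap=len(overlap),
                overlap_proteins=frozenset(overlap),
                p_value=p,
            )
        )
    results.sort(key=lambda r: (r.p_value, r.pathway_id))
    return results


def benjamini_hochberg(p_values: Sequence[float]) -> np.ndarray:
    """BH-adjusted q-values, preserving input order."""
    p = np.asarray(p_values, dtype=np.float64)
    m = p.size
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    running = 1.0
    for rank_from_end, idx in enumerate(order[::-1]):
        rank = m - rank_from_end
        running = min(running, p[idx] * m / rank)
        q[idx] = running
    return q


def results_to_frame(results: Sequence[EnrichmentResult], bh: bool = False) -> pd.DataFrame:
    df = pd.DataFrame(
        {
            "pathway_id": [r.pathway_id for r in results],
            "pathway_size": [r.pathway_size for r in results],
            "overlap": [r.overlap for r in results],
            "overlap_proteins": [",".join(sorted(r.overlap_proteins)) for r in results],
            "p_value": [r.p_value for r in results],
        }
    )
    if bh and len(df):
        df["bh_fdr"] = benjamini_hochberg(df["p_value"].to_numpy())
    return df


def restrict_to_universe(pmap: PathwayMap, eligible_ids) -> PathwayMap:
    """Intersect pathway members with an eligible protein set.

    Used to build the conventional ORA universe (e.g. structure-solved
    AND pathway-mapped proteins): members outside the eligible set are
    dropped, empty pathways vanish, and N becomes the count of eligible
    proteins that carry at least one annotation.
    """
    eligible = set(eligible_ids)
    union = set().union(*pmap.pathways.values()) if pmap.pathways else set()
    members = {
        pid: mem & eligible for pid, mem in pmap.pathways.items() if mem & eligible
    }
    return PathwayMap(
        pathways=members,
        universe_size=len(union & eligible),
        descriptions={pid: pmap.descriptions.get(pid, "") for pid in members},
    )


def read_gmt(path, universe_size: int | None = None) -> PathwayMap:
    """Parse a GMT file (pathway_id <TAB> description <TAB> member ids...).

    Without an explicit ``universe_size`` the universe defaults to the
    union of all pathway members.
    """
    pathways: dict[str, set[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed GMT line: {line[:80]!r}")
            pid, desc, members = parts[0], parts[1], [m for m in parts[2:] if m]
            if pid in pathways:
                raise ValueError(f"duplicate pathway id {pid!r}")
            pathways[pid] = set(members)
            descriptions[pid] = desc
    union = set().union(*pathways.values()) if pathways else set()
    return PathwayMap(
        pathways=pathways,
        universe_size=len(union) if universe_size is None else universe_size,
        descriptions=descriptions,
    )


def write_gmt(pmap: PathwayMap, path) -> None:
    with open(path, "w") as fh:
        for pid in sorted(pmap.pathways):
            desc = pmap.descriptions.get(pid, "")
            members = "\t".join(sorted(pmap.pathways[pid]))
            fh.write(f"{pid}\t{desc}\t{members}\n")
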