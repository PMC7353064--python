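"""GO term over-representation with Benjamini--Hochberg adjustment.

For a study set of n proteins drawn from a background of N, a term
annotating K background proteins and k study proteins is scored with the
one-sided hypergeometric upper tail P(X >= k) (Fisher's exact test, greater
alternative). Raw p-values are adjusted across all tested terms by the BH
step-up procedure; the reported subset keeps terms with adjusted p below
``bh_alpha`` that annotate at least ``min_annotated`` study proteins.
Enrichments are also expressed as -log10(adjusted p) for plotting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .core import CriteriaConfig

__all__ = ["EnrichmentResult", "hypergeom_upper_tail", "bh_adjust", "enrich"]


def hypergeom_upper_tail(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n).

    ``N`` is the background size, ``K`` the background proteins annotated by
    the term, ``n`` the study size, ``k`` the study proteins annotated.
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"invalid urn: K={K}, n={n}, N={N}")
    if not 0 <= k <= min(K, n):
        raise ValueError(f"invalid hit count k={k} for K={K}, n={n}")
    if k == 0:
        return 1.0  # certain event; also covers the empty urn N = 0
    # sf(k-1) = P(X >= k); scipy computes the tail with stable log terms
    return float(hypergeom.sf(k - 1, N, K, n))


def bh_adjust(p_values: Sequence[float]) -> list[float]:
    """Benjamini--Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1].tolist()


@dataclass(frozen=True)
class EnrichmentResult:
    """Per-term enrichment outcome.

    ``k``/``n`` are study hits and study size; ``K``/``N`` the background
    analogues. ``significant`` marks membership in the reported subset
    (adjusted p below alpha and at least ``min_annotated`` study hits).
    """

    go_id: str
    name: str
    k: int
    n: int
    K: int
    N: int
    p_raw: float
    p_bh: float
    significant: bool
    annotated_symbols: tuple[str, ...]

    @property
    def neg_log10_bh(self) -> float:
        if self.p_bh <= 0.0:
            return math.inf
        return -math.log10(self.p_bh)


def enrich(
    study: Iterable[str],
    background: Iterable[str],
    annotations: Mapping[str, Iterable[str]],
    config: CriteriaConfig | None = None,
    term_names: Mapping[str, str] | None = None,
) -> list[EnrichmentResult]:
    """Test every GO term with at least one study hit.

    Parameters
    ----------
    study, background
        Symbol sets; the study must be a subset of the background.
    annotations
        ``go_id -> annotated symbols`` (e.g. from
        :func:`secretalk.io_formats.annotation_map`). Annotated symbols
        outside the background are ignored.
    config
        Supplies ``bh_alpha`` and ``min_annotated`` for the reported subset.
    term_names
        Optional ``go_id -> human-readable name``.

    Returns all tested terms sorted by adjusted p (ties by term id), each
    flagged ``significant`` or not. The BH family is the set of tested terms
    in this call.
    """
    config = config or CriteriaConfig()
    term_names = term_names or {}
    study_set = set(study)
    bg_set = set(background)
    if not bg_set:
        raise ValueError("empty background")
    offenders = study_set - bg_set
    if offenders:
        raise ValueError(f"study symbols absent from background: {sorted(offenders)[:10]}")
    N, n = len(bg_set), len(study_set)
    tested: list[tuple[str, int, int, tuple[str, ...], float]] = []
    for go_id in sorted(annotations):
        ann = set(annotations[go_id]) & bg_set
        hits = tuple(sorted(ann & study_set))
        if not hits:
            continue
        K, k = len(ann), len(hits)
        tested.append((go_id, k, K, hits, hypergeom_upper_tail(k, K, n, N)))
    adjusted = bh_adjust([t[4] for t in tested])
    results = [
        EnrichmentResult(
            go_id=go_id,
            name=term_names.get(go_id, ""),
            k=k,
            n=n,
            K=K,
            N=N,
            p_raw=p_raw,
            p_bh=p_bh,
            significant=(p_bh < config.bh_alpha and k >= config.min_annotated),
            annotated_symbols=hits,
        )
        for (go_id, k, K, hits, p_raw), p_bh in zip(tested, adjusted)
    ]
    results.sort(key=lambda r: (r.p_bh, r.go_id))
    return results
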