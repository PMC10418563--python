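"""Modified cosine similarity between MS/MS spectra.

The modified cosine pairs fragment peaks either at (nearly) equal m/z
("direct" pairs) or offset by the precursor mass difference
Δ = precursor(query) − precursor(reference) ("shifted" pairs, enabled for
analog search). Each peak participates in at most one selected pair; the
score is

    score = Σ_selected w_q(i) · w_r(j) / (‖w_q‖ · ‖w_r‖)

with the norms running over ALL peaks of each spectrum, so the score lies in
[0, 1] and equals 1 exactly for a spectrum against itself. Peak weights
default to sqrt(intensity) (common molecular-networking practice) and are
configurable to raw intensity or intensity^p · mz^q.

Pair selection is greedy descending by pair weight with deterministic
tie-breaking (smaller query index, then smaller reference index). An exact
maximum-weight one-to-one assignment (scipy's linear-sum assignment) is
available via ``method="exact"`` and serves as the optimality oracle in
tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .exceptions import UndefinedScoreError
from .spectra_io import Spectrum

__all__ = [
    "PeakPair",
    "SimilarityResult",
    "candidate_pairs",
    "modified_cosine",
    "mirror_plot_table",
    "write_mirror_plot",
]

class PeakPair(NamedTuple):
    """A scored pairing of query peak index vs reference peak index."""

    query: int
    ref: int
    shifted: bool
    weight: float


@dataclass(frozen=True)
class SimilarityResult:
    """Outcome of one spectrum-vs-spectrum comparison."""

    score: float
    n_matched: int
    delta_mz: float
    pairs: tuple[PeakPair, ...]


def peak_weights(spectrum: Spectrum, weighting="sqrt") -> np.ndarray:
    """Per-peak weights under the configured scheme.

    ``"sqrt"`` → sqrt(intensity); ``"raw"`` → intensity; a ``(p, q)`` tuple →
    intensity**p * mz**q.
    """
    if weighting == "sqrt":
        return np.sqrt(spectrum.intensity)
    if weighting == "raw":
        return spectrum.intensity.astype(float)
    if isinstance(weighting, (tuple, list)) and len(weighting) == 2:
        p, q = weighting
        return spectrum.intensity**p * spectrum.mz**q
    raise ValueError(f"unknown weighting {weighting!r}")


def candidate_pairs(
    q: Spectrum,
    r: Spectrum,
    frag_tol: float = 0.05,
    allow_shift: bool = False,
    weighting="sqrt",
) -> list[PeakPair]:
    """All peak pairs within ``frag_tol`` directly, plus Δ-shifted pairs.

    Direct pairs satisfy |mz_q − mz_r| <= frag_tol; shifted pairs (only when
    ``allow_shift``) satisfy |mz_q − mz_r − Δ| <= frag_tol with
    Δ = precursor_q − precursor_r. A (query, ref) index combination that
    qualifies both ways is emitted once, flagged direct. Pair weight is
    w_q(i) · w_r(j).
    """
    if frag_tol <= 0:
        raise ValueError("frag_tol must be > 0")
    if q.is_empty or r.is_empty:
        return []
    wq = peak_weights(q, weighting)
    wr = peak_weights(r, weighting)
    diff = q.mz[:, None] - r.mz[None, :]
    direct = np.abs(diff) <= frag_tol
    pairs: list[PeakPair] = []
    delta = q.precursor_mz - r.precursor_mz
    if allow_shift:
        shifted = np.abs(diff - delta) <= frag_tol
        shifted &= ~direct  # direct classification takes precedence
    for i, j in zip(*np.nonzero(direct)):
        pairs.append(PeakPair(int(i), int(j), False, float(wq[i] * wr[j])))
    if allow_shift:
        for i, j in zip(*np.nonzero(shifted)):
            pairs.append(PeakPair(int(i), int(j), True, float(wq[i] * wr[j])))
    pairs.sort(key=lambda p: (p.query, p.ref))
    return pairs


def _select_greedy(pairs: Sequence[PeakPair], nq: int, nr: int) -> list[PeakPair]:
    chosen: list[PeakPair] = []
    used_q = np.zeros(nq, dtype=bool)
    used_r = np.zeros(nr, dtype=bool)
    for p in sorted(pairs, key=lambda p: (-p.weight, p.query, p.ref)):
        if not used_q[p.query] and not used_r[p.ref]:
            chosen.append(p)
            used_q[p.query] = True
            used_r[p.ref] = True
    chosen.sort(key=lambda p: (p.query, p.ref))
    return chosen


def _select_exact(pairs: Sequence[PeakPair], nq: int, nr: int) -> list[PeakPair]:
    # Max-weight one-to-one assignment restricted to candidate pairs. All
    # candidate weights are >= 0, so padding the matrix with zeros and
    # maximizing recovers the optimal matching over candidates only.
    weight = np.zeros((nq, nr))
    lookup: dict[tuple[int, int], PeakPair] = {}
    for p in pairs:
        if p.weight >= weight[p.query, p.ref]:
            weight[p.query, p.ref] = p.weight
            lookup[(p.query, p.ref)] = p
    rows, cols = linear_sum_assignment(weight, maximize=True)
    chosen = [lookup[(i, j)] for i, j in zip(rows, cols) if (i, j) in lookup]
    chosen.sort(key=lambda p: (p.query, p.ref))
    return chosen


def modified_cosine(
    q: Spectrum,
    r: Spectrum,
    frag_tol: float = 0.05,
    allow_shift: bool = False,
    weighting="sqrt",
    method: str = "greedy",
) -> SimilarityResult:
    """Modified cosine score and matched-ion count between two spectra.

    ``method="greedy"`` (default) selects pairs greedily by descending
    weight; ``method="exact"`` solves the maximum-weight assignment exactly.
    Raises `UndefinedScoreError` when both spectra are empty.
    """
    if q.is_empty and r.is_empty:
        raise UndefinedScoreError("similarity of two empty spectra is undefined")
    delta = q.precursor_mz - r.precursor_mz
    wq = peak_weights(q, weighting)
    wr = peak_weights(r, weighting)
    norm = float(np.linalg.norm(wq) * np.linalg.norm(wr))
    pairs = candidate_pairs(q, r, frag_tol=frag_tol, allow_shift=allow_shift, weighting=weighting)
    if not pairs or norm == 0.0:
        return SimilarityResult(0.0, 0, delta, ())
    if method == "greedy":
        chosen = _select_greedy(pairs, len(q), len(r))
    elif method == "exact":
        chosen = _select_exact(pairs, len(q), len(r))
    else:
        raise ValueError(f"unknown pairing method {method!r}")
    score = min(1.0, sum(p.weight for p in chosen) / norm)
    return SimilarityResult(float(score), len(chosen), delta, tuple(chosen))


def mirror_plot_table(q: Spectrum, r: Spectrum, pairs: Sequence[PeakPair]) -> pd.DataFrame:
    """Tabulate scored pairs for mirror-plot rendering."""
    rows = [
        {
            "mz_q": float(q.mz[p.query]),
            "int_q": float(q.intensity[p.query]),
            "mz_r": float(r.mz[p.ref]),
            "int_r": float(r.intensity[p.ref]),
            "pair_type": "shifted" if p.shifted else "direct",
        }
        for p in pairs
    ]
    return pd.DataFrame(rows, columns=["mz_q", "int_q", "mz_r", "int_r", "pair_type"])


def write_mirror_plot(q: Spectrum, r: Spectrum, pairs: Sequence[PeakPair], path: str | Path) -> None:
    mirror_plot_table(q, r, pairs).to_csv(path, sep="\t", index=False)
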