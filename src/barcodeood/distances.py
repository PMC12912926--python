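"""Genetic distances and distance-based identification / OOD detection.

Two distance modes are provided:

* ``k2p`` — the Kimura 2-parameter distance on aligned sequences, which
  corrects the observed transition proportion P and transversion proportion Q
  for multiple hits:  d = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q).
  Sites where either sequence carries a non-canonical letter are excluded
  (pairwise deletion); pairs overlapping on fewer than half of the alignment
  are flagged undefined (NaN) and saturated pairs (log argument <= 0) are
  flagged +inf.

* ``identity`` — a blastn-like percent similarity for unaligned inputs,
  computed from the best local alignment under match=+1, mismatch=-2,
  gap open=-5, gap extend=-2; the distance is (100 - %identity)/100.

Identification follows the 1-nearest-neighbor rule; OOD detection follows a
best-close-match-style rule with per-species thresholds taken as the 95%
quantile of within-species minimum distances.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from numba import njit

from .dataset import (
    GenusDataset,
    SequenceRecord,
    SplitDataset,
    encode_codes,
)

__all__ = [
    "k2p_distance",
    "k2p_matrix",
    "k2p_cross",
    "percent_identity",
    "pairwise_distances",
    "nn_classify",
    "distance_thresholds",
    "query_calibrated_thresholds",
    "distance_ood_flag",
    "popgen_metrics",
    "perfect_bounds",
    "PopGenMetrics",
    "PerfectBounds",
]

MIN_OVERLAP = 0.5


# ---------------------------------------------------------------------------
# K2P
# ---------------------------------------------------------------------------

def _k2p_from_pq(P: np.ndarray, Q: np.ndarray) -> np.ndarray:
    """Closed-form K2P distance from transition/transversion proportions."""
    a = 1.0 - 2.0 * P - Q
    b = 1.0 - 2.0 * Q
    with np.errstate(divide="ignore", invalid="ignore"):
        d = -0.5 * np.log(a) - 0.25 * np.log(b)
    bad = (a <= 0) | (b <= 0)
    return np.where(bad, np.inf, d)


def _as_codes(seq) -> np.ndarray:
    if isinstance(seq, str):
        return encode_codes([seq])[0]
    return np.asarray(seq, dtype=np.uint8)


def k2p_distance(a, b, min_overlap: float = MIN_OVERLAP) -> float:
    """K2P distance between two aligned sequences (strings or uint8 codes).

    Returns +inf for saturated pairs and NaN when fewer than ``min_overlap``
    of the alignment columns are jointly canonical; raises on zero overlap.
    """
    ca, cb = _as_codes(a), _as_codes(b)
    if ca.shape != cb.shape:
        raise ValueError("sequences must have equal aligned length")
    valid = (ca != 255) & (cb != 255)
    n_valid = int(valid.sum())
    if n_valid == 0:
        raise ValueError("no jointly canonical sites; distance undefined")
    if n_valid < min_overlap * ca.size:
        return float("nan")
    va, vb = ca[valid], cb[valid]
    diff = va != vb
    transitions = int(np.sum(diff & ((va ^ vb) == 2)))
    transversions = int(diff.sum()) - transitions
    return float(_k2p_from_pq(
        np.float64(transitions / n_valid), np.float64(transversions / n_valid)
    ))


def _base_indicators(codes: np.ndarray) -> np.ndarray:
    """Stack of float32 indicator matrices for bases A, C, G, T: (4, n, L)."""
    return np.stack([(codes == b).astype(np.float32) for b in range(4)])


def _pq_counts(ind_a: np.ndarray, ind_b: np.ndarray):
    """Pairwise valid-site, transition and transversion counts via matmuls."""
    valid_a = ind_a.sum(axis=0)
    valid_b = ind_b.sum(axis=0)
    n_valid = valid_a @ valid_b.T
    matches = sum(ind_a[b] @ ind_b[b].T for b in range(4))
    # transitions: A<->G and C<->T
    ts = (
        ind_a[0] @ ind_b[2].T + ind_a[2] @ ind_b[0].T
        + ind_a[1] @ ind_b[3].T + ind_a[3] @ ind_b[1].T
    )
    tv = n_valid - matches - ts
    return n_valid, ts, tv


def _k2p_block(codes_a: np.ndarray, codes_b: np.ndarray, length: int) -> np.ndarray:
    n_valid, ts, tv = _pq_counts(_base_indicators(codes_a), _base_indicators(codes_b))
    # counts are integers (exact in float32); divide in float64 so the
    # matrix path agrees with the scalar path to full precision
    n_valid = n_valid.astype(np.float64)
    with np.errstate(divide="ignore", invalid="ignore"):
        P = ts.astype(np.float64) / n_valid
        Q = tv.astype(np.float64) / n_valid
    d = _k2p_from_pq(P, Q)
    d = np.where(n_valid == 0, np.nan, d)
    d = np.where(n_valid < MIN_OVERLAP * length, np.nan, d)
    return d


def k2p_matrix(dataset_or_codes) -> np.ndarray:
    """Symmetric pairwise K2P matrix (float64, zero diagonal)."""
    codes = (
        dataset_or_codes.encode()
        if isinstance(dataset_or_codes, GenusDataset)
        else np.asarray(dataset_or_codes, dtype=np.uint8)
    )
    d = _k2p_block(codes, codes, codes.shape[1])
    np.fill_diagonal(d, 0.0)
    return d


def k2p_cross(codes_q: np.ndarray, codes_r: np.ndarray) -> np.ndarray:
    """K2P distances between every query row and every reference row."""
    codes_q = np.asarray(codes_q, dtype=np.uint8)
    codes_r = np.asarray(codes_r, dtype=np.uint8)
    return _k2p_block(codes_q, codes_r, codes_q.shape[1])


# ---------------------------------------------------------------------------
# Local-alignment percent identity (blastn-like scoring)
# ---------------------------------------------------------------------------

MATCH, MISMATCH, GAP_OPEN, GAP_EXTEND = 1.0, -2.0, -5.0, -2.0


@njit(cache=True)
def _sw_identity(a, b, match, mismatch, gap_open, gap_extend):  # pragma: no cover
    """Smith-Waterman with affine gaps; returns (matches, columns, score).

    A gap of length k costs -(gap_open + k*gap_extend) in magnitude terms,
    i.e. opening applies once on top of the per-residue extension.
    """
    n, m = a.shape[0], b.shape[0]
    NEG = -1e18
    H = np.zeros((n + 1, m + 1))
    E = np.full((n + 1, m + 1), NEG)  # gap in a (move along b)
    F = np.full((n + 1, m + 1), NEG)  # gap in b (move along a)
    # traceback pointers: 0 stop, 1 diag, 2 from E, 3 from F
    ptr_h = np.zeros((n + 1, m + 1), dtype=np.uint8)
    ptr_e = np.zeros((n + 1, m + 1), dtype=np.uint8)  # 1 open, 0 extend
    ptr_f = np.zeros((n + 1, m + 1), dtype=np.uint8)
    best = 0.0
    bi, bj = 0, 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            e_open = H[i, j - 1] + gap_open + gap_extend
            e_ext = E[i, j - 1] + gap_extend
            if e_open >= e_ext:
                E[i, j] = e_open
                ptr_e[i, j] = 1
            else:
                E[i, j] = e_ext
            f_open = H[i - 1, j] + gap_open + gap_extend
            f_ext = F[i - 1, j] + gap_extend
            if f_open >= f_ext:
                F[i, j] = f_open
                ptr_f[i, j] = 1
            else:
                F[i, j] = f_ext
            s = match if a[i - 1] == b[j - 1] else mismatch
            diag = H[i - 1, j - 1] + s
            h = 0.0
            p = 0
            if diag > h:
                h = diag
                p = 1
            if E[i, j] > h:
                h = E[i, j]
                p = 2
            if F[i, j] > h:
                h = F[i, j]
                p = 3
            H[i, j] = h
            ptr_h[i, j] = p
            if h > best:
                best = h
                bi, bj = i, j
    # traceback
    matches = 0
    columns = 0
    i, j = bi, bj
    state = 0  # 0: in H, 2: in E, 3: in F
    while i > 0 and j > 0:
        if state == 0:
            p = ptr_h[i, j]
            if p == 0:
                break
            if p == 1:
                columns += 1
                if a[i - 1] == b[j - 1]:
                    matches += 1
                i -= 1
                j -= 1
            else:
                state = p
        elif state == 2:
            columns += 1
            opened = ptr_e[i, j]
            j -= 1
            if opened == 1:
                state = 0
        else:
            columns += 1
            opened = ptr_f[i, j]
            i -= 1
            if opened == 1:
                state = 0
    return matches, columns, best


@njit(cache=True)
def _sw_identity_batch(qcodes, rcodes):  # pragma: no cover
    """Identity distance for every query/reference pair (DP buffers reused)."""
    nq, nr = qcodes.shape[0], rcodes.shape[0]
    out = np.empty((nq, nr))
    for i in range(nq):
        for j in range(nr):
            matches, columns, score = _sw_identity(
                qcodes[i], rcodes[j], MATCH, MISMATCH, GAP_OPEN, GAP_EXTEND
            )
            if columns == 0 or score <= 0:
                out[i, j] = 1.0
            else:
                out[i, j] = 1.0 - matches / columns
    return out


def percent_identity(a: str, b: str) -> float:
    """Percent identity of the best blastn-like local alignment of two sequences.

    Works on unaligned inputs; gap characters are stripped first. Returns
    100 * matches / alignment-columns, or 0.0 when no positive-scoring local
    alignment exists.
    """
    sa = a.replace("-", "").replace(".", "")
    sb = b.replace("-", "").replace(".", "")
    if not sa or not sb:
        raise ValueError("empty sequence")
    ca = np.frombuffer(sa.upper().encode("ascii"), dtype=np.uint8)
    cb = np.frombuffer(sb.upper().encode("ascii"), dtype=np.uint8)
    matches, columns, score = _sw_identity(
        ca, cb, MATCH, MISMATCH, GAP_OPEN, GAP_EXTEND
    )
    if columns == 0 or score <= 0:
        return 0.0
    return 100.0 * matches / columns


def _identity_distance_cross(queries: list[str], references: list[str]) -> np.ndarray:
    def clean(seqs):
        return [s.replace("-", "").replace(".", "").upper() for s in seqs]

    qs, rs = clean(queries), clean(references)
    if any(not s for s in qs + rs):
        raise ValueError("empty sequence")
    qlen = {len(s) for s in qs}
    rlen = {len(s) for s in rs}
    if len(qlen) == 1 and len(rlen) == 1:
        # uniform lengths: run the whole batch inside the compiled kernel
        qc = np.frombuffer("".join(qs).encode("ascii"), dtype=np.uint8).reshape(
            len(qs), qlen.pop()
        )
        rc = np.frombuffer("".join(rs).encode("ascii"), dtype=np.uint8).reshape(
            len(rs), rlen.pop()
        )
        return _sw_identity_batch(qc, rc)
    out = np.empty((len(qs), len(rs)))
    for i, q in enumerate(qs):
        for j, r in enumerate(rs):
            out[i, j] = (100.0 - percent_identity(q, r)) / 100.0
    return out


def pairwise_distances(
    queries: list[SequenceRecord],
    references: list[SequenceRecord],
    metric: str = "k2p",
) -> np.ndarray:
    """Query-by-reference distance matrix under the chosen metric."""
    if metric == "k2p":
        return k2p_cross(
            encode_codes(r.sequence for r in queries),
            encode_codes(r.sequence for r in references),
        )
    if metric == "identity":
        return _identity_distance_cross(
            [r.sequence for r in queries], [r.sequence for r in references]
        )
    raise ValueError(f"unknown metric {metric!r}")


# ---------------------------------------------------------------------------
# 1NN identification and best-close-match OOD thresholds
# ---------------------------------------------------------------------------

def _nn_from_matrix(dist: np.ndarray, references: list[SequenceRecord]):
    """Nearest reference per query row; ties go to the smallest sample_id."""
    ref_ids = np.array([r.sample_id for r in references])
    order = np.argsort(ref_ids, kind="stable")
    dist_sorted = dist[:, order]
    with np.errstate(invalid="ignore"):
        clean = np.where(np.isnan(dist_sorted), np.inf, dist_sorted)
    nn_idx = order[np.argmin(clean, axis=1)]
    nn_dist = clean.min(axis=1)
    labels = np.array([references[i].species for i in nn_idx])
    return labels, nn_dist, nn_idx


def nn_classify(
    query, references: list[SequenceRecord], metric: str = "k2p"
) -> tuple[str, float]:
    """Assign a query to the species of its nearest reference record."""
    if not references:
        raise ValueError("empty reference collection")
    if isinstance(query, SequenceRecord):
        queries, single = [query], True
    else:
        queries, single = list(query), False
    dist = pairwise_distances(queries, references, metric)
    labels, nn_dist, _ = _nn_from_matrix(dist, references)
    if single:
        return str(labels[0]), float(nn_dist[0])
    return labels, nn_dist


def _quantile(values: np.ndarray, q: float) -> float:
    # type-7 (linear interpolation), numpy's default
    return float(np.quantile(np.asarray(values, dtype=float), q))


def distance_thresholds(
    references: list[SequenceRecord], metric: str = "k2p", q: float = 0.95
) -> dict[str, float]:
    """Per-species OOD cutoffs from leave-one-out within-species minima.

    For every reference record the minimum distance to its conspecific
    references is computed; the species threshold is the ``q`` quantile of
    those minima. Singleton species get an infinite threshold with a warning.
    """
    by_species: dict[str, list[SequenceRecord]] = {}
    for r in references:
        by_species.setdefault(r.species, []).append(r)
    thresholds: dict[str, float] = {}
    for species, recs in sorted(by_species.items()):
        if len(recs) < 2:
            warnings.warn(f"species {species!r} has a single reference; threshold set to +inf")
            thresholds[species] = float("inf")
            continue
        dist = pairwise_distances(recs, recs, metric)
        np.fill_diagonal(dist, np.inf)
        minima = np.where(np.isnan(dist), np.inf, dist).min(axis=1)
        thresholds[species] = _quantile(minima, q)
    return thresholds


def query_calibrated_thresholds(
    calibration: list[SequenceRecord],
    references: list[SequenceRecord],
    metric: str = "k2p",
    q: float = 0.95,
) -> dict[str, float]:
    """Per-species cutoffs from held-out ID samples' distances to conspecific references.

    Mirrors the uncertainty-score calibration: each held-out ID sample
    contributes its minimum distance to same-species references, and the
    species threshold is the ``q`` quantile of those minima. Calibrating on
    held-out (possibly noisy) material keeps the threshold matched to the
    test-time distance distribution.
    """
    classes = sorted({r.species for r in calibration})
    thresholds: dict[str, float] = {}
    for species in classes:
        cal = [r for r in calibration if r.species == species]
        refs = [r for r in references if r.species == species]
        if not refs:
            warnings.warn(f"no references for species {species!r}; threshold +inf")
            thresholds[species] = float("inf")
            continue
        dist = pairwise_distances(cal, refs, metric)
        minima = np.where(np.isnan(dist), np.inf, dist).min(axis=1)
        thresholds[species] = _quantile(minima, q)
    return thresholds


def distance_ood_flag(
    queries: list[SequenceRecord],
    references: list[SequenceRecord],
    thresholds: dict[str, float],
    metric: str = "k2p",
):
    """Flag queries whose nearest-neighbor distance exceeds the NN species' cutoff.

    Returns (labels, nn_distances, is_ood); the comparison is strict, so a
    query exactly at the threshold is accepted as ID.
    """
    dist = pairwise_distances(queries, references, metric)
    labels, nn_dist, _ = _nn_from_matrix(dist, references)
    cut = np.array([thresholds[l] for l in labels])
    return labels, nn_dist, nn_dist > cut


# ---------------------------------------------------------------------------
# Population-genetic metrics and perfect-classifier bounds
# ---------------------------------------------------------------------------

@dataclass
class PopGenMetrics:
    """Summary statistics driving identification difficulty for one genus."""

    n_classes: int
    dw_avg: float
    dbt_avg: float
    dbt_min: float
    completeness: float
    samples_per_species: float

    def as_dict(self) -> dict[str, float]:
        return {
            "n_classes": self.n_classes,
            "dw_avg": self.dw_avg,
            "dbt_avg": self.dbt_avg,
            "dbt_min": self.dbt_min,
            "completeness": self.completeness,
            "samples_per_species": self.samples_per_species,
        }


def _nanmean(values: np.ndarray) -> float:
    finite = values[np.isfinite(values)]
    if finite.size < values.size:
        warnings.warn("undefined distances excluded from population-genetic means")
    return float(finite.mean()) if finite.size else float("nan")


def popgen_metrics(dataset: GenusDataset) -> PopGenMetrics:
    """Within/between-species K2P summaries, completeness and sampling depth.

    Within-species distance is averaged per ID species and then across
    species; between-species distances are averaged per ID species pair, with
    the minimum taken over pairs.
    """
    id_recs = dataset.id_records
    if not id_recs:
        raise ValueError("partitions not assigned or no ID species")
    id_species = sorted({r.species for r in id_recs})
    codes = {
        sp: encode_codes(r.sequence for r in id_recs if r.species == sp)
        for sp in id_species
    }
    dw = []
    for sp in id_species:
        c = codes[sp]
        if c.shape[0] < 2:
            continue
        d = k2p_matrix(c)
        dw.append(_nanmean(d[np.triu_indices(c.shape[0], k=1)]))
    pair_means = []
    for i, sp_a in enumerate(id_species):
        for sp_b in id_species[i + 1:]:
            d = k2p_cross(codes[sp_a], codes[sp_b])
            pair_means.append(_nanmean(d.ravel()))
    pair_means = np.array(pair_means) if pair_means else np.array([np.nan])
    n_total_species = len(dataset.species)
    return PopGenMetrics(
        n_classes=len(id_species),
        dw_avg=float(np.mean(dw)) if dw else float("nan"),
        dbt_avg=float(np.nanmean(pair_means)),
        dbt_min=float(np.nanmin(pair_means)),
        completeness=len(id_species) / n_total_species,
        samples_per_species=len(id_recs) / len(id_species),
    )


@dataclass
class PerfectBounds:
    """Error floors set by sequences identical across the ID/OOD boundary.

    ``accuracy_upper`` is 1 minus the fraction of ID test samples whose exact
    sequence occurs among heterospecific training references (no
    sequence-based classifier can distinguish those from the wrong species).
    ``fnr_lower`` is the fraction of OOD samples sequence-identical to at
    least one ID sample (no sequence-based detector can flag those).
    """

    accuracy_upper: float
    fnr_lower: float


def perfect_bounds(split: SplitDataset, ties: str = "error") -> PerfectBounds:
    """Zero-distance bounds of a split dataset on its current window.

    ``ties`` controls how a test sample identical to both conspecific and
    heterospecific references is counted: ``"error"`` (default) treats any
    heterospecific zero-distance match as a forced error, which makes
    ``accuracy_upper`` exactly monotone non-increasing under window
    truncation; ``"identifiable"`` grants the oracle the true class (the
    loosest valid ceiling, but not monotone); ``"half"`` splits the
    difference.
    """
    if ties not in ("error", "identifiable", "half"):
        raise ValueError("ties must be 'error', 'identifiable' or 'half'")
    train_by_seq: dict[str, set[str]] = {}
    for r in split.train_id:
        train_by_seq.setdefault(r.sequence, set()).add(r.species)
    tie_weight = {"error": 1.0, "identifiable": 0.0, "half": 0.5}[ties]
    forced_errors = 0.0
    for r in split.test_id:
        species_here = train_by_seq.get(r.sequence)
        if species_here is None or species_here == {r.species}:
            continue
        if r.species not in species_here:
            forced_errors += 1.0
        else:
            forced_errors += tie_weight
    accuracy_upper = 1.0 - forced_errors / len(split.test_id) if split.test_id else 1.0

    id_seqs = {r.sequence for r in split.train_id} | {r.sequence for r in split.test_id}
    if split.ood:
        fnr_lower = sum(r.sequence in id_seqs for r in split.ood) / len(split.ood)
    else:
        fnr_lower = 0.0
    return PerfectBounds(accuracy_upper=accuracy_upper, fnr_lower=fnr_lower)
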