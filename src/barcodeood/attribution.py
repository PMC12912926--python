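"""Gradient attribution on nucleotide alignments.

Grad-CAM localizes the alignment regions driving a classification decision:
the target-class logit is backpropagated to the last convolutional block's
feature maps, channel weights are the position-averaged gradients, and the
rectified weighted sum of feature maps is linearly upsampled back to the
input length and max-normalized per sample. Grad-energy runs the identical
pipeline with the energy score as the backpropagated scalar, localizing the
regions driving the OOD decision instead; no target class is involved.

Attribution tracks are summarized in non-overlapping windows (8 bp by
default) and compared with per-window nucleotide diversity (16 bp windows)
of the alignment.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import softmax
from scipy.stats import pearsonr

from .dataset import encode_codes

__all__ = [
    "gradcam",
    "grad_energy",
    "mean_track",
    "window_mean",
    "window_diversity",
    "correlate_tracks",
]


def _tracks_from_grads(maps: np.ndarray, grads: np.ndarray, out_length: int) -> np.ndarray:
    """Rectified gradient-weighted feature-map sum, upsampled and normalized."""
    weights = grads.mean(axis=2)  # (n, channels)
    cam = np.einsum("nc,ncl->nl", weights, maps)
    cam = np.maximum(cam, 0.0)
    n, coarse = cam.shape
    xp = (np.arange(coarse) + 0.5) / coarse
    x = (np.arange(out_length) + 0.5) / out_length
    tracks = np.stack([np.interp(x, xp, cam[i]) for i in range(n)])
    peak = tracks.max(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        tracks = np.where(peak > 0, tracks / peak, 0.0)
    return tracks


def _attribution(model, records, dlogits_fn, batch: int = 128) -> np.ndarray:
    if not getattr(model, "trained", True):
        raise ValueError("attribution requires a trained model")
    records = list(records)
    length = model.spec.input_length
    out = []
    for start in range(0, len(records), batch):
        chunk = records[start:start + batch]
        maps, logits = model.feature_maps_and_logits(chunk)
        dlogits = dlogits_fn(logits, chunk)
        grads = model.backprop_to_feature_maps(dlogits)
        tracks = _tracks_from_grads(maps, grads, model.spec.padded_length)
        out.append(tracks[:, :length])
    return np.concatenate(out) if out else np.empty((0, length))


def gradcam(model, records, target_class: str | None = None) -> np.ndarray:
    """Per-sample Grad-CAM tracks, shape (n, L), values in [0, 1].

    The backpropagated scalar is the logit of ``target_class`` or, by
    default, of each sample's predicted class.
    """
    if target_class is not None and target_class not in model.classes:
        raise ValueError(f"unknown class {target_class!r}")

    def dlogits_fn(logits: np.ndarray, chunk) -> np.ndarray:
        d = np.zeros_like(logits)
        if target_class is None:
            idx = logits.argmax(axis=1)
        else:
            idx = np.full(logits.shape[0], model.classes.index(target_class))
        d[np.arange(logits.shape[0]), idx] = 1.0
        return d

    return _attribution(model, records, dlogits_fn)


def grad_energy(model, records, temperature: float = 1.0) -> np.ndarray:
    """Per-sample grad-energy tracks: Grad-CAM with the energy score as scalar."""

    def dlogits_fn(logits: np.ndarray, chunk) -> np.ndarray:
        # d/dlogit_k of -T*logsumexp(logits/T) = -softmax(logits/T)_k
        return -softmax(logits / temperature, axis=1)

    return _attribution(model, records, dlogits_fn)


def mean_track(tracks: np.ndarray) -> np.ndarray:
    """Average of normalized per-sample tracks (the figure-style summary)."""
    return np.asarray(tracks).mean(axis=0)


def window_mean(track: np.ndarray, width: int = 8) -> pd.DataFrame:
    """Non-overlapping window means of a track; a trailing partial window is kept.

    Returns columns (start, width, mean_score, partial).
    """
    track = np.asarray(track, dtype=float)
    if width < 1 or track.size < width:
        raise ValueError("window width must be >= 1 and <= track length")
    rows = []
    for start in range(0, track.size, width):
        chunk = track[start:start + width]
        rows.append(
            {
                "start": start,
                "width": len(chunk),
                "mean_score": float(chunk.mean()),
                "partial": len(chunk) < width,
            }
        )
    return pd.DataFrame(rows)


def window_diversity(alignment, width: int = 16) -> pd.DataFrame:
    """Per-window nucleotide diversity of an alignment.

    For every site the mean pairwise mismatch proportion among samples with
    canonical bases is computed (pairwise deletion); the window value is the
    average over its sites, i.e. mean pairwise differences per site. Sites
    with fewer than two canonical bases contribute zero diversity.
    Accepts a GenusDataset, a list of records/strings, or a code matrix.
    """
    if hasattr(alignment, "encode"):
        codes = alignment.encode()
    elif isinstance(alignment, np.ndarray):
        codes = alignment.astype(np.uint8)
    else:
        codes = encode_codes(
            r.sequence if hasattr(r, "sequence") else r for r in alignment
        )
    n, length = codes.shape
    if width < 1 or length < width:
        raise ValueError("window width must be >= 1 and <= alignment length")
    counts = np.stack([(codes == b).sum(axis=0) for b in range(4)])  # (4, L)
    valid = counts.sum(axis=0)
    pairs = valid * (valid - 1) / 2.0
    same = (counts * (counts - 1) / 2.0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        pi = np.where(pairs > 0, (pairs - same) / pairs, 0.0)
    rows = []
    for start in range(0, length, width):
        chunk = pi[start:start + width]
        rows.append(
            {
                "start": start,
                "width": len(chunk),
                "diversity": float(chunk.mean()),
                "partial": len(chunk) < width,
            }
        )
    return pd.DataFrame(rows)


def correlate_tracks(
    score_windows: pd.DataFrame, diversity_windows: pd.DataFrame
) -> float:
    """Pearson correlation between window attribution scores and diversity.

    Score windows on a finer grid are aggregated onto the diversity grid by
    averaging (e.g. pairs of 8-bp windows onto 16-bp windows). Returns NaN
    when either vector is constant.
    """
    div = diversity_windows["diversity"].to_numpy(dtype=float)
    if score_windows.shape[0] != div.size:
        # aggregate each finer score window onto the coarser diversity window
        # containing its start (partial trailing windows included)
        dwidth = int(diversity_windows["width"].iloc[0])
        grouped = score_windows.groupby(score_windows["start"] // dwidth)[
            "mean_score"
        ].mean()
        scores = grouped.reindex(range(div.size)).to_numpy(dtype=float)
        if np.any(np.isnan(scores)):
            raise ValueError("score and diversity windows are not on nested grids")
    else:
        scores = score_windows["mean_score"].to_numpy(dtype=float)
    if np.allclose(scores, scores[0]) or np.allclose(div, div[0]):
        return float("nan")
    return float(pearsonr(scores, div).statistic)
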