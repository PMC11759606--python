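"""Slide-level feature fusion: patch-likelihood histogram (PLH) and BoW/TF-IDF.

Each slide's bag of patch likelihoods is summarized twice:

* PLH — a 101-bin normalized histogram of the likelihoods on [0, 1];
* BoW — each patch is quantized to one of the same 101 bins ("words"); the
  slide is the tf-idf vector of its word counts, with idf fitted on the
  training slides and frozen for test slides.

Each pipeline contributes 101 probability features plus 2 predictive-label
features (majority-vote patch label, thresholded mean likelihood), for a
fused vector of exactly 2 x (101 + 2) = 206 named features per slide.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
import json

import numpy as np
import pandas as pd

N_BINS = 101

PLH_NAMES = [f"plh_{k:03d}" for k in range(N_BINS)] + ["plh_label_major", "plh_label_meanprob"]
BOW_NAMES = [f"bow_{k:03d}" for k in range(N_BINS)] + ["bow_label_major", "bow_label_meanprob"]
FEATURE_NAMES = PLH_NAMES + BOW_NAMES  # length 206, stable order


def _check_bag(likelihoods: np.ndarray) -> np.ndarray:
    arr = np.asarray(likelihoods, dtype=float).ravel()
    if arr.size == 0:
        raise ValueError("empty likelihood bag")
    if np.any((arr < 0) | (arr > 1)):
        raise ValueError("likelihoods must lie in [0, 1]")
    return arr


def quantize(likelihoods: np.ndarray) -> np.ndarray:
    """Bin index in 0..100 with equal-width bins [k/101, (k+1)/101); last bin closed."""
    arr = _check_bag(likelihoods)
    return np.minimum((arr * N_BINS).astype(int), N_BINS - 1)


def plh_features(likelihoods: np.ndarray) -> np.ndarray:
    """Normalized 101-bin histogram of one slide's patch likelihoods (sums to 1)."""
    counts = np.bincount(quantize(likelihoods), minlength=N_BINS).astype(float)
    return counts / counts.sum()


@dataclass
class BowTfidf:
    """TF-IDF encoder over the 101 quantization words.

    idf uses the smoothed convention ``ln((1 + N)/(1 + df)) + 1`` over the N
    fitting (training) slides and is frozen afterwards; tf is the within-slide
    word frequency count(w)/bag size.
    """

    idf: np.ndarray | None = None
    n_fit_slides: int = 0

    def fit(self, bags: list[np.ndarray]) -> "BowTfidf":
        if len(bags) == 0:
            raise ValueError("need at least one slide to fit idf")
        df = np.zeros(N_BINS)
        for bag in bags:
            df += np.bincount(np.unique(quantize(bag)), minlength=N_BINS)
        n = len(bags)
        self.idf = np.log((1.0 + n) / (1.0 + df)) + 1.0
        self.n_fit_slides = n
        return self

    def transform(self, bag: np.ndarray) -> np.ndarray:
        if self.idf is None:
            raise ValueError("idf not fitted; call fit() on the training slides first")
        if len(self.idf) != N_BINS:
            raise ValueError(f"vocabulary size mismatch: idf has {len(self.idf)} words")
        words = quantize(bag)
        tf = np.bincount(words, minlength=N_BINS).astype(float) / len(words)
        return tf * self.idf

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "idf": self.idf.tolist(), "n_fit_slides": self.n_fit_slides,
            "n_bins": N_BINS, "bin_rule": "k/101 equal width, last bin closed",
        }))

    @classmethod
    def from_json(cls, path: str | Path) -> "BowTfidf":
        d = json.loads(Path(path).read_text())
        if d["n_bins"] != N_BINS:
            raise ValueError(f"vocabulary size mismatch: file has {d['n_bins']} bins")
        return cls(idf=np.asarray(d["idf"]), n_fit_slides=int(d["n_fit_slides"]))


def bow_tfidf(bags: dict[str, np.ndarray], fit_slides: list[str] | None = None
              ) -> dict[str, np.ndarray]:
    """TF-IDF vectors for every slide, idf fitted on ``fit_slides`` (default: all)."""
    fit_ids = list(bags) if fit_slides is None else list(fit_slides)
    enc = BowTfidf().fit([bags[s] for s in fit_ids])
    return {s: enc.transform(bag) for s, bag in bags.items()}


def label_features(likelihoods: np.ndarray, pred_labels: np.ndarray | None = None
                   ) -> np.ndarray:
    """The two predictive-label features of one slide.

    (majority vote of hard patch labels — ties resolve to 1 — and the
    indicator that the mean likelihood is >= 0.5).
    """
    arr = _check_bag(likelihoods)
    if pred_labels is None:
        pred_labels = (arr >= 0.5).astype(int)
    pred_labels = np.asarray(pred_labels, dtype=int)
    majority = 1 if pred_labels.mean() >= 0.5 else 0
    return np.array([majority, 1 if arr.mean() >= 0.5 else 0], dtype=float)


def assemble_features(plh: np.ndarray, plh_labels: np.ndarray,
                      bow: np.ndarray, bow_labels: np.ndarray) -> np.ndarray:
    """Concatenate the four blocks into the 206-vector (order fixed by FEATURE_NAMES)."""
    for block, expect in ((plh, N_BINS), (plh_labels, 2), (bow, N_BINS), (bow_labels, 2)):
        if len(np.asarray(block).ravel()) != expect:
            raise ValueError(f"block of length {len(np.asarray(block).ravel())}, expected {expect}")
    return np.concatenate([np.ravel(plh), np.ravel(plh_labels),
                           np.ravel(bow), np.ravel(bow_labels)])


def slide_feature_table(preds: pd.DataFrame, train_slides: list[str] | None = None
                        ) -> tuple[pd.DataFrame, BowTfidf]:
    """Fuse a patch-prediction table into one 206-feature row per slide.

    ``preds`` has columns slide_id, likelihood, pred_label.  idf is fitted on
    ``train_slides`` (default: every slide present) and returned for freezing.
    Row order follows first appearance of each slide in ``preds``.
    """
    slide_ids = list(pd.unique(preds["slide_id"]))
    bags = {s: preds.loc[preds["slide_id"] == s, "likelihood"].to_numpy()
            for s in slide_ids}
    hard = {s: preds.loc[preds["slide_id"] == s, "pred_label"].to_numpy()
            for s in slide_ids}
    fit_ids = [s for s in (train_slides if train_slides is not None else slide_ids)
               if s in bags]
    if not fit_ids:
        raise ValueError("no training slides present in the prediction table")
    enc = BowTfidf().fit([bags[s] for s in fit_ids])
    rows = []
    for s in slide_ids:
        lf = label_features(bags[s], hard[s])
        rows.append(assemble_features(plh_features(bags[s]), lf, enc.transform(bags[s]), lf))
    table = pd.DataFrame(rows, columns=FEATURE_NAMES)
    table.insert(0, "slide_id", slide_ids)
    return table, enc
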