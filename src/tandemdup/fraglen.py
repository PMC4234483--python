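"""Empirical fragment-length distribution.

Concordant (FR) pairs measure the sequenced fragment directly: the outer span
``e + r - s`` of a concordant pair equals the fragment length under the
fragment convention used throughout this package.  The model is a trimmed
histogram over ``[l_min, l_max]`` with a per-cell pseudocount so that every
in-range length has positive probability (the breakpoint score is a product
of these probabilities, and a single empty histogram cell must not zero it).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Union

import numpy as np

NEG_INF = float("-inf")


class FragmentModelError(RuntimeError):
    pass


@dataclass
class FragmentLengthModel:
    """Probability mass over integer fragment lengths in ``[l_min, l_max]``."""

    l_min: int
    l_max: int
    counts: np.ndarray          # raw counts per length, length l_max-l_min+1
    pseudocount: float = 0.5
    _log_pmf: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if self.l_min > self.l_max:
            raise FragmentModelError(f"l_min={self.l_min} > l_max={self.l_max}")
        self.counts = np.asarray(self.counts, dtype=float)
        if len(self.counts) != self.l_max - self.l_min + 1:
            raise FragmentModelError("counts length does not match [l_min, l_max]")
        if np.any(self.counts < 0) or self.pseudocount < 0:
            raise FragmentModelError("negative counts or pseudocount")
        smoothed = self.counts + self.pseudocount
        total = smoothed.sum()
        if total <= 0:
            raise FragmentModelError("model has zero total mass; use pseudocount > 0")
        self._pmf = smoothed / total
        with np.errstate(divide="ignore"):
            self._log_pmf = np.log(self._pmf)

    @property
    def support(self) -> np.ndarray:
        return np.arange(self.l_min, self.l_max + 1)

    def pmf(self, length: Union[int, np.ndarray]):
        length = np.asarray(length)
        inside = (length >= self.l_min) & (length <= self.l_max)
        idx = np.clip(length - self.l_min, 0, len(self._pmf) - 1)
        out = np.where(inside, self._pmf[idx], 0.0)
        return float(out) if out.ndim == 0 else out

    def log_pmf(self, length: Union[int, np.ndarray]):
        """log pmf; lengths outside [l_min, l_max] get the -inf sentinel."""
        length = np.asarray(length)
        inside = (length >= self.l_min) & (length <= self.l_max)
        idx = np.clip(length - self.l_min, 0, len(self._log_pmf) - 1)
        out = np.where(inside, self._log_pmf[idx], NEG_INF)
        return float(out) if out.ndim == 0 else out

    @property
    def mean(self) -> float:
        return float(np.dot(self.support, self._pmf))

    @property
    def sd(self) -> float:
        return float(np.sqrt(np.dot((self.support - self.mean) ** 2, self._pmf)))

    # -- serialization ------------------------------------------------------

    def save(self, path: Union[str, os.PathLike]) -> None:
        with open(path, "w") as fh:
            fh.write(f"#l_min={self.l_min}\n#l_max={self.l_max}\n")
            fh.write(f"#pseudocount={self.pseudocount!r}\n")
            fh.write("length\tcount\n")
            for l, c in zip(self.support, self.counts):
                fh.write(f"{l}\t{c:g}\n")

    @classmethod
    def load(cls, path: Union[str, os.PathLike]) -> "FragmentLengthModel":
        meta = {}
        lengths, counts = [], []
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if line.startswith("#"):
                    k, v = line[1:].split("=", 1)
                    meta[k] = v
                elif line and not line.startswith("length\t"):
                    l, c = line.split("\t")
                    lengths.append(int(l))
                    counts.append(float(c))
        l_min, l_max = int(meta["l_min"]), int(meta["l_max"])
        arr = np.zeros(l_max - l_min + 1)
        for l, c in zip(lengths, counts):
            arr[l - l_min] = c
        return cls(l_min=l_min, l_max=l_max, counts=arr,
                   pseudocount=float(meta.get("pseudocount", 0.5)))


def fit_lengths(
    lengths: np.ndarray,
    trim_quantile: float = 0.001,
    pseudocount: float = 0.5,
    min_pairs: int = 100,
) -> FragmentLengthModel:
    """Fit the model from raw observed fragment lengths.

    ``l_min``/``l_max`` are the ``trim_quantile`` and ``1 - trim_quantile``
    empirical quantiles (outermost order statistics when trimming is 0);
    observations outside are dropped.  Trimming protects the histogram
    bounds — and hence the size of every breakpoint trapezoid — from rare
    chimeric outliers.
    """
    lengths = np.asarray(lengths, dtype=np.int64)
    if len(lengths) < min_pairs:
        raise FragmentModelError(
            f"only {len(lengths)} concordant pairs; at least {min_pairs} required "
            "to fit the fragment-length distribution"
        )
    if not (0 <= trim_quantile < 0.5):
        raise FragmentModelError(f"trim_quantile must be in [0, 0.5), got {trim_quantile}")
    l_min = int(np.quantile(lengths, trim_quantile, method="lower"))
    l_max = int(np.quantile(lengths, 1.0 - trim_quantile, method="higher"))
    kept = lengths[(lengths >= l_min) & (lengths <= l_max)]
    counts = np.bincount(kept - l_min, minlength=l_max - l_min + 1).astype(float)
    return FragmentLengthModel(l_min=l_min, l_max=l_max, counts=counts,
                               pseudocount=pseudocount)


def fit(
    concordant,
    trim_quantile: float = 0.001,
    pseudocount: float = 0.5,
    min_pairs: int = 100,
) -> FragmentLengthModel:
    """Fit from concordant pairs (a PairSet or iterable of records).

    The observed length of each pair is its outer span ``e + r - s``.
    """
    from .pairs import PairSet

    if isinstance(concordant, PairSet):
        spans = concordant.spans
    else:
        spans = np.array([p.span for p in concordant], dtype=np.int64)
    return fit_lengths(spans, trim_quantile=trim_quantile,
                       pseudocount=pseudocount, min_pairs=min_pairs)
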