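"""In-memory genotype container shared by every stage of the toolkit.

Genotypes are stored as allele dosages of the counted allele (PLINK A1 /
VCF ALT): each call is 0, 1 or 2 copies, with ``MISSING`` (-1) marking a
failed call.  Markers are kept sorted by (chromosome, position) so that
physical-distance pruning can rely on coordinate order.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import FormatError

#: Sentinel for a missing genotype call in the int8 dosage matrix.
MISSING: int = -1

MARKER_COLUMNS = ["id", "chrom", "pos", "a1", "a2"]
SAMPLE_COLUMNS = ["id", "population"]

#: Population label given to samples that are not reference animals.
TARGET_LABEL = "TARGET"


def chrom_sort_key(label) -> tuple:
    """Sort key for chromosome labels: numeric labels first in numeric
    order, everything else lexicographic afterwards."""
    s = str(label)
    if s.lower().startswith("chr"):
        s = s[3:]
    if s.isdigit():
        return (0, int(s), "")
    return (1, 0, s)


@dataclass
class GenotypeMatrix:
    """Samples x markers dosage matrix with marker map and sample labels.

    Attributes
    ----------
    calls:
        ``int8`` array of shape (n_samples, n_markers); values in
        {0, 1, 2, MISSING}.
    markers:
        DataFrame with columns ``id, chrom, pos, a1, a2`` (a1 is the
        counted allele), sorted by (chromosome, position).
    samples:
        DataFrame with columns ``id, population``.
    """

    calls: np.ndarray
    markers: pd.DataFrame
    samples: pd.DataFrame

    # ------------------------------------------------------------------
    @classmethod
    def create(cls, calls, markers: pd.DataFrame, samples: pd.DataFrame) -> "GenotypeMatrix":
        """Validate inputs, sort markers by genome coordinate and build."""
        calls = np.asarray(calls)
        if calls.dtype != np.int8:
            calls = calls.astype(np.int8)
        markers = markers.reset_index(drop=True).copy()
        samples = samples.reset_index(drop=True).copy()
        gm = cls(calls, markers, samples)
        gm._sort_markers()
        gm.validate()
        return gm

    def _sort_markers(self) -> None:
        keys = [
            (chrom_sort_key(c), int(p), str(i))
            for c, p, i in zip(self.markers["chrom"], self.markers["pos"], self.markers["id"])
        ]
        order = sorted(range(len(keys)), key=keys.__getitem__)
        if order != list(range(len(keys))):
            idx = np.asarray(order)
            self.calls = np.ascontiguousarray(self.calls[:, idx])
            self.markers = self.markers.iloc[idx].reset_index(drop=True)

    def validate(self) -> None:
        if self.calls.ndim != 2:
            raise FormatError("calls must be a 2-D matrix")
        n, m = self.calls.shape
        if len(self.samples) != n or len(self.markers) != m:
            raise FormatError(
                f"calls shape {self.calls.shape} inconsistent with "
                f"{len(self.samples)} samples / {len(self.markers)} markers"
            )
        for col in MARKER_COLUMNS:
            if col not in self.markers.columns:
                raise FormatError(f"marker table missing column {col!r}")
        for col in SAMPLE_COLUMNS:
            if col not in self.samples.columns:
                raise FormatError(f"sample table missing column {col!r}")
        bad = ~np.isin(self.calls, (0, 1, 2, MISSING))
        if bad.any():
            raise FormatError("genotype calls outside {0,1,2,missing}")
        if m and (self.markers["pos"].to_numpy() < 1).any():
            raise FormatError("marker positions must be 1-based (>= 1)")
        if m and (self.markers["a1"].astype(str) == self.markers["a2"].astype(str)).any():
            raise FormatError("counted and other allele must differ")
        if (self.samples["population"].astype(str).str.len() == 0).any():
            raise FormatError("empty population label")

    # ------------------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.calls.shape[0]

    @property
    def n_markers(self) -> int:
        return self.calls.shape[1]

    def calls_float(self) -> np.ndarray:
        """Dosages as float64 with NaN for missing calls."""
        x = self.calls.astype(np.float64)
        x[self.calls == MISSING] = np.nan
        return x

    def marker_index(self, marker_ids) -> np.ndarray:
        """Column indices for the given marker ids (KeyError if absent)."""
        lookup = pd.Series(np.arange(self.n_markers), index=self.markers["id"])
        missing = [m for m in marker_ids if m not in lookup.index]
        if missing:
            raise KeyError(f"markers absent from genotype matrix: {missing[:5]}")
        return lookup.loc[list(marker_ids)].to_numpy()

    def subset_markers(self, index) -> "GenotypeMatrix":
        idx = np.asarray(index)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return GenotypeMatrix.create(
            self.calls[:, idx], self.markers.iloc[idx], self.samples
        )

    def subset_samples(self, index) -> "GenotypeMatrix":
        idx = np.asarray(index)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return GenotypeMatrix(
            np.ascontiguousarray(self.calls[idx]),
            self.markers.copy(),
            self.samples.iloc[idx].reset_index(drop=True),
        )
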