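"""Domain types and preprocessing for lipid-nanoparticle formulation data.

An exosome-mimetic nanoparticle (ENP) formulation is described by the molar
percentages of five lipid classes (cholesterol, sphingomyelin,
phosphatidylcholine, phosphatidylethanolamine, phosphatidylserine) summing to
100 — the critical material attributes (CMAs) — optionally paired with three
measured critical quality attributes (CQAs): hydrodynamic size (nm),
polydispersity index, and zeta potential (mV).

This module provides the record/dataset containers, CSV I/O, and the
preprocessing chain: composition normalization, robust outlier removal,
quantile-bin undersampling balance, and the train/blind split.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Optional, Sequence

import numpy as np
import pandas as pd

LIPIDS: tuple[str, ...] = ("chol", "sm", "pc", "pe", "ps")
CQAS: tuple[str, ...] = ("size_nm", "pdi", "zeta_mv")
PROVENANCES: tuple[str, ...] = ("experimental", "gan_synthetic", "generator_truth")

#: tolerance on the simplex-closure constraint (components sum to 100)
SIMPLEX_TOL = 1e-6


class FormulationError(ValueError):
    """Base class for formulation-data errors."""


class DegenerateCompositionError(FormulationError):
    pass


class InsufficientDataError(FormulationError):
    pass


class FormatError(FormulationError):
    pass


class BinningError(FormulationError):
    pass


@dataclass(frozen=True)
class LipidComposition:
    """One lipid composition, mol% on the 0–100 scale, closed to 100."""

    chol: float
    sm: float
    pc: float
    pe: float
    ps: float

    def __post_init__(self) -> None:
        arr = self.as_array()
        if np.any(arr < 0):
            raise FormulationError(f"negative lipid fraction in {arr}")
        total = float(arr.sum())
        if abs(total - 100.0) > SIMPLEX_TOL:
            raise FormulationError(
                f"composition must sum to 100 within {SIMPLEX_TOL}; got {total!r}"
            )

    def as_array(self) -> np.ndarray:
        return np.array([self.chol, self.sm, self.pc, self.pe, self.ps], dtype=float)

    @classmethod
    def from_array(cls, arr: Sequence[float]) -> "LipidComposition":
        if len(arr) != 5:
            raise FormulationError("a composition has exactly five components")
        return cls(*(float(v) for v in arr))


@dataclass(frozen=True)
class CQAVector:
    """Measured (or predicted) quality attributes of one formulation."""

    size_nm: float
    pdi: float
    zeta_mv: float

    def __post_init__(self) -> None:
        if not self.size_nm > 0:
            raise FormulationError(f"size_nm must be > 0, got {self.size_nm}")
        if self.pdi < 0:
            raise FormulationError(f"pdi must be >= 0, got {self.pdi}")

    def as_array(self) -> np.ndarray:
        return np.array([self.size_nm, self.pdi, self.zeta_mv], dtype=float)


@dataclass(frozen=True)
class FormulationRecord:
    composition: LipidComposition
    cqa: Optional[CQAVector] = None
    provenance: str = "experimental"

    def __post_init__(self) -> None:
        if self.provenance not in PROVENANCES:
            raise FormulationError(
                f"provenance must be one of {PROVENANCES}, got {self.provenance!r}"
            )


class FormulationDataset:
    """Ordered collection of formulation records, backed by a DataFrame.

    Columns: the five lipids, optionally the three CQAs, and ``provenance``.
    An optional ``split_labels`` array tags every record 'train' or 'blind'.
    """

    def __init__(self, frame: pd.DataFrame, split_labels: Optional[np.ndarray] = None):
        missing = [c for c in LIPIDS if c not in frame.columns]
        if missing:
            raise FormatError(f"missing lipid column(s): {missing}")
        if "provenance" not in frame.columns:
            frame = frame.assign(provenance="experimental")
        bad = ~frame["provenance"].isin(PROVENANCES)
        if bad.any():
            raise FormatError(
                f"unknown provenance at row(s) {list(frame.index[bad][:5])}"
            )
        self._frame = frame.reset_index(drop=True)
        if split_labels is not None:
            split_labels = np.asarray(split_labels, dtype=object)
            if len(split_labels) != len(self._frame):
                raise FormulationError("split labels must cover every record")
        self.split_labels = split_labels

    # -- construction -----------------------------------------------------
    @classmethod
    def from_records(cls, records: Sequence[FormulationRecord]) -> "FormulationDataset":
        rows = []
        for r in records:
            row = dict(zip(LIPIDS, r.composition.as_array()))
            if r.cqa is not None:
                row.update(zip(CQAS, r.cqa.as_array()))
            row["provenance"] = r.provenance
            rows.append(row)
        return cls(pd.DataFrame(rows))

    @classmethod
    def from_arrays(
        cls,
        compositions: np.ndarray,
        cqas: Optional[np.ndarray] = None,
        provenance: str = "experimental",
    ) -> "FormulationDataset":
        frame = pd.DataFrame(np.asarray(compositions, dtype=float), columns=list(LIPIDS))
        if cqas is not None:
            for j, name in enumerate(CQAS):
                frame[name] = np.asarray(cqas, dtype=float)[:, j]
        frame["provenance"] = provenance
        return cls(frame)

    # -- access -----------------------------------------------------------
    def __len__(self) -> int:
        return len(self._frame)

    @property
    def frame(self) -> pd.DataFrame:
        return self._frame

    @property
    def has_cqas(self) -> bool:
        return all(c in self._frame.columns for c in CQAS) and not (
            self._frame[list(CQAS)].isna().any().any()
        )

    def compositions(self) -> np.ndarray:
        return self._frame[list(LIPIDS)].to_numpy(dtype=float)

    def cqas(self) -> np.ndarray:
        if not all(c in self._frame.columns for c in CQAS):
            raise FormulationError("dataset has no CQA columns")
        return self._frame[list(CQAS)].to_numpy(dtype=float)

    def records(self) -> Iterator[FormulationRecord]:
        has = all(c in self._frame.columns for c in CQAS)
        for _, row in self._frame.iterrows():
            comp = LipidComposition(*(float(row[c]) for c in LIPIDS))
            cqa = None
            if has and not any(pd.isna(row[c]) for c in CQAS):
                cqa = CQAVector(*(float(row[c]) for c in CQAS))
            yield FormulationRecord(comp, cqa, str(row["provenance"]))

    def subset(self, indices: np.ndarray) -> "FormulationDataset":
        return FormulationDataset(self._frame.iloc[np.asarray(indices)].copy())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FormulationDataset):
            return NotImplemented
        return self._frame.equals(other._frame)


# -- operations -----------------------------------------------------------

def normalize_composition(raw: Sequence[float]) -> LipidComposition:
    """Close five nonnegative amounts to the 100% simplex.

    Proportions are preserved; an all-zero input has no direction on the
    simplex and raises :class:`DegenerateCompositionError`.
    """
    arr = np.asarray(raw, dtype=float)
    if arr.shape != (5,):
        raise FormulationError("expected exactly five components")
    if np.any(arr < 0):
        raise FormulationError("components must be nonnegative")
    total = arr.sum()
    if total <= 0:
        raise DegenerateCompositionError("all-zero composition cannot be normalized")
    return LipidComposition.from_array(arr * (100.0 / total))


def remove_outliers(ds: FormulationDataset, k: float = 3.5) -> FormulationDataset:
    """Drop records with any CQA beyond ``k`` robust deviations of its median.

    The robust scale is 1.4826·MAD (consistent with the standard deviation
    under normality). A zero-MAD component keeps only values exactly at the
    median, which preserves constant datasets untouched. The filter is
    iterated to a fixed point so that re-applying it is a no-op. Refuses to
    remove more than half of the original records.
    """
    if not ds.has_cqas:
        raise FormulationError("outlier removal requires CQAs on every record")
    if len(ds) < 10:
        raise InsufficientDataError(f"need >= 10 records, got {len(ds)}")
    if k <= 0:
        raise FormulationError("k must be positive")
    n0 = len(ds)
    current = ds
    while True:
        values = current.cqas()
        med = np.median(values, axis=0)
        scale = 1.4826 * np.median(np.abs(values - med), axis=0)
        keep = (np.abs(values - med) <= k * scale + SIMPLEX_TOL).all(axis=1)
        if keep.sum() < 0.5 * n0:
            raise FormulationError(
                f"outlier rule would remove more than 50% of {n0} records"
            )
        if keep.all():
            return current
        current = current.subset(np.flatnonzero(keep))


def _rank_bins(values: np.ndarray, n_bins: int) -> np.ndarray:
    """Equal-count quantile bins by ordinal rank (deterministic, tie-stable)."""
    n = len(values)
    if n_bins > n:
        raise BinningError(f"{n_bins} bins requested for {n} records: empty bin")
    order = np.argsort(values, kind="stable")
    ranks = np.empty(n, dtype=int)
    ranks[order] = np.arange(n)
    return (ranks * n_bins) // n


def _quantile_bins_ties_together(values: np.ndarray, n_bins: int) -> np.ndarray:
    """Quantile bins that never split tied values.

    Each distinct value is assigned the bin of its mean ordinal rank, so for
    all-distinct data this is exact equal-count binning (and therefore a
    no-op when re-applied to balanced output), while tied clusters stay in
    one bin.
    """
    n = len(values)
    if n_bins > n:
        raise BinningError(f"{n_bins} bins requested for {n} records: empty bin")
    uniq, inverse, counts = np.unique(values, return_inverse=True, return_counts=True)
    # mean ordinal rank of each distinct value
    ends = np.cumsum(counts)
    mean_ranks = ends - (counts + 1) / 2.0
    group_bins = (mean_ranks * n_bins // n).astype(int)
    return group_bins[inverse]


def balance_by_undersampling(
    ds: FormulationDataset,
    n_bins: int = 10,
    target_cqa: str = "size_nm",
    seed: int = 0,
) -> FormulationDataset:
    """Balance a continuous target by quantile-bin undersampling.

    Records are binned by quantiles of the chosen CQA (ties stay together);
    every bin is randomly downsampled (seeded) to the smallest bin's count.
    Record order is preserved, so re-applying with the same parameters is a
    no-op on already-balanced data with distinct values.
    """
    if n_bins < 2:
        raise FormulationError("n_bins must be >= 2")
    if target_cqa not in CQAS:
        raise FormulationError(f"unknown CQA {target_cqa!r}")
    if not ds.has_cqas:
        raise FormulationError("balancing requires CQAs")
    values = ds.frame[target_cqa].to_numpy(dtype=float)
    bins = _quantile_bins_ties_together(values, n_bins)
    counts = np.bincount(bins, minlength=n_bins)
    if (counts == 0).any():
        raise BinningError("empty quantile bin")
    m = int(counts.min())
    rng = np.random.default_rng(seed)
    keep: list[np.ndarray] = []
    for b in range(n_bins):
        members = np.flatnonzero(bins == b)
        if len(members) > m:
            members = rng.choice(members, size=m, replace=False)
        keep.append(members)
    idx = np.sort(np.concatenate(keep))
    return ds.subset(idx)


def split_dataset(
    ds: FormulationDataset,
    train_frac: float = 0.7,
    seed: int = 0,
    stratify_on: Optional[str] = None,
    n_strata: int = 10,
) -> tuple[FormulationDataset, FormulationDataset]:
    """Random (optionally quantile-stratified) train/blind partition.

    The train size is ``round(n * train_frac)`` exactly; with stratification
    the per-bin allocation follows largest-remainder rounding so per-bin
    proportions match ``train_frac`` within one record.
    """
    n = len(ds)
    if n < 2:
        raise InsufficientDataError("cannot split fewer than 2 records")
    if not 0 < train_frac < 1:
        raise FormulationError("train_frac must be in (0, 1)")
    n_train = int(round(n * train_frac))
    n_train = min(max(n_train, 1), n - 1)
    rng = np.random.default_rng(seed)

    if stratify_on is None:
        perm = rng.permutation(n)
        train_idx = np.sort(perm[:n_train])
    else:
        values = ds.frame[stratify_on].to_numpy(dtype=float)
        bins = _rank_bins(values, min(n_strata, n))
        targets = {}
        fracs = {}
        for b in np.unique(bins):
            exact = np.count_nonzero(bins == b) * train_frac
            targets[b] = int(np.floor(exact))
            fracs[b] = exact - np.floor(exact)
        deficit = n_train - sum(targets.values())
        for b in sorted(fracs, key=lambda b: (-fracs[b], b))[: max(deficit, 0)]:
            targets[b] += 1
        picks = []
        for b in np.unique(bins):
            members = np.flatnonzero(bins == b)
            picks.append(rng.choice(members, size=targets[b], replace=False))
        train_idx = np.sort(np.concatenate(picks))

    mask = np.zeros(n, dtype=bool)
    mask[train_idx] = True
    return ds.subset(np.flatnonzero(mask)), ds.subset(np.flatnonzero(~mask))


# -- CSV I/O ---------------------------------------------------------------

def read_csv(path) -> FormulationDataset:
    """Read a formulation CSV (comma-separated, dot decimal, header required)."""
    frame = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in LIPIDS if c not in frame.columns]
    if missing:
        raise FormatError(f"missing lipid column(s): {missing}")
    comp = frame[list(LIPIDS)].to_numpy(dtype=float)
    neg_rows = np.flatnonzero((comp < 0).any(axis=1))
    if len(neg_rows):
        raise FormatError(f"negative lipid fraction at row {int(neg_rows[0])}")
    sums = comp.sum(axis=1)
    bad = np.flatnonzero(np.abs(sums - 100.0) > 0.5)
    if len(bad):
        raise FormatError(
            f"row {int(bad[0])} sums to {sums[bad[0]]:.4g}, not 100 (tolerance 0.5)"
        )
    keep = [c for c in (*LIPIDS, *CQAS, "provenance") if c in frame.columns]
    return FormulationDataset(frame[keep].copy())


def write_csv(ds: FormulationDataset, path) -> None:
    ds.frame.to_csv(path, index=False)
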