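"""In-memory containers and I/O for barcode-level MPRA count data.

An MPRA experiment measures thousands of candidate regulatory sequences
("elements"), each linked to several DNA barcodes.  Sequencing the plasmid
DNA and the transcribed RNA yields two barcode x sample count matrices; the
log2 ratio of RNA to DNA abundance is the activity measure of an element.
This module holds those counts together with sample metadata, performs
total-count library-size normalization, and applies the standard low-count
filters ahead of modeling.

Canonical file dialect: tab-separated, header row of sample ids, first
column the barcode id; the element map is two columns (barcode, element);
the sample sheet has columns ``sample``, ``condition`` and optionally
``block``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "MpraFormatError",
    "SampleSheet",
    "BarcodeCountSet",
    "ElementActivityMatrix",
    "FilterReport",
    "read_counts",
    "write_counts",
    "total_count_normalize",
    "filter_elements",
]


class MpraFormatError(ValueError):
    """Raised when input tables violate the expected layout or invariants."""


# ---------------------------------------------------------------------------
# sample metadata
# ---------------------------------------------------------------------------

@dataclass
class SampleSheet:
    """Per-sample metadata: condition labels and optional block (pair) ids.

    Blocks identify samples that share a biological unit, e.g. the two
    alleles of a variant measured in the same transfection; every block must
    contain at least two samples.
    """

    sample_ids: list[str]
    condition: pd.Series
    block: pd.Series | None = None
    covariates: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.condition = pd.Series(
            np.asarray(self.condition), index=self.sample_ids, name="condition"
        )
        if self.condition.nunique() < 1:
            raise MpraFormatError("condition must have at least one level")
        if self.block is not None:
            self.block = pd.Series(
                np.asarray(self.block), index=self.sample_ids, name="block"
            )
            sizes = self.block.value_counts()
            if (sizes < 2).any():
                bad = sizes[sizes < 2].index.tolist()
                raise MpraFormatError(f"blocks with fewer than 2 samples: {bad}")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame({"condition": self.condition}, index=self.sample_ids)
        if self.block is not None:
            frame["block"] = self.block
        if self.covariates is not None:
            frame = frame.join(self.covariates)
        frame.index.name = "sample"
        return frame

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "SampleSheet":
        if "condition" not in frame.columns:
            raise MpraFormatError("sample sheet requires a 'condition' column")
        block = frame["block"] if "block" in frame.columns else None
        extra = frame.drop(columns=[c for c in ("condition", "block") if c in frame])
        return cls(
            sample_ids=list(frame.index.astype(str)),
            condition=frame["condition"],
            block=block,
            covariates=extra if extra.shape[1] else None,
        )


# ---------------------------------------------------------------------------
# barcode-level counts
# ---------------------------------------------------------------------------

@dataclass
class BarcodeCountSet:
    """Barcode x sample RNA and DNA counts plus sample metadata.

    ``barcode_to_element`` maps every barcode id to exactly one element id;
    the number of barcodes per element (B) may vary.  Library sizes default
    to the column sums of the respective matrix.  After
    :func:`total_count_normalize` the per-sample scale factors ``L/N`` and
    the common library size ``L`` are recorded; raw integer counts are kept
    and scaling is applied lazily inside the activity estimators.
    """

    rna: pd.DataFrame
    dna: pd.DataFrame
    barcode_to_element: pd.Series
    samples: SampleSheet
    rna_lib_sizes: pd.Series | None = None
    dna_lib_sizes: pd.Series | None = None
    common_lib_size: float | None = None

    def __post_init__(self) -> None:
        if self.rna.shape != self.dna.shape:
            raise MpraFormatError(
                f"rna shape {self.rna.shape} != dna shape {self.dna.shape}"
            )
        if list(self.rna.columns) != list(self.dna.columns):
            raise MpraFormatError("rna and dna sample columns disagree")
        if list(self.rna.index) != list(self.dna.index):
            raise MpraFormatError("rna and dna barcode ordering disagree")
        if list(self.rna.columns) != list(self.samples.sample_ids):
            raise MpraFormatError("count columns do not match the sample sheet")
        for name, mat in (("rna", self.rna), ("dna", self.dna)):
            values = mat.to_numpy()
            if not np.issubdtype(values.dtype, np.number):
                raise MpraFormatError(f"{name} counts are not numeric")
            if (values < 0).any():
                raise MpraFormatError(f"{name} contains negative counts")
            if not np.allclose(values, np.round(values)):
                raise MpraFormatError(f"{name} contains non-integer counts")
        self.barcode_to_element = pd.Series(self.barcode_to_element)
        missing = self.rna.index.difference(self.barcode_to_element.index)
        if len(missing):
            raise MpraFormatError(
                f"barcodes without an element mapping: {list(missing[:5])}"
            )
        self.barcode_to_element = self.barcode_to_element.loc[self.rna.index]
        if self.rna_lib_sizes is None:
            self.rna_lib_sizes = self.rna.sum(axis=0).astype(float)
        if self.dna_lib_sizes is None:
            self.dna_lib_sizes = self.dna.sum(axis=0).astype(float)
        self.rna_lib_sizes = pd.Series(self.rna_lib_sizes, index=self.rna.columns, dtype=float)
        self.dna_lib_sizes = pd.Series(self.dna_lib_sizes, index=self.dna.columns, dtype=float)

    # -- basic accessors ----------------------------------------------------

    @property
    def element_ids(self) -> list:
        seen: dict = {}
        for e in self.barcode_to_element.to_numpy():
            seen.setdefault(e, None)
        return list(seen)

    @property
    def barcode_ids(self) -> list:
        return list(self.rna.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.rna.columns)

    @property
    def n_barcodes_per_element(self) -> pd.Series:
        return self.barcode_to_element.value_counts().reindex(self.element_ids)

    @property
    def is_normalized(self) -> bool:
        return self.common_lib_size is not None

    @property
    def rna_scale(self) -> pd.Series:
        """Per-sample RNA scale factors L / N_r."""
        self._require_normalized()
        return self.common_lib_size / self.rna_lib_sizes

    @property
    def dna_scale(self) -> pd.Series:
        """Per-sample DNA scale factors L / N_d."""
        self._require_normalized()
        return self.common_lib_size / self.dna_lib_sizes

    def _require_normalized(self) -> None:
        if not self.is_normalized:
            raise MpraFormatError(
                "counts have not been normalized; call total_count_normalize first"
            )

    def aggregated(self, which: str) -> pd.DataFrame:
        """Element x sample counts summed over barcodes (raw scale)."""
        mat = {"rna": self.rna, "dna": self.dna}[which]
        agg = mat.groupby(self.barcode_to_element.to_numpy(), sort=False).sum()
        return agg.reindex(self.element_ids)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, BarcodeCountSet):
            return NotImplemented
        return (
            self.rna.equals(other.rna)
            and self.dna.equals(other.dna)
            and self.barcode_to_element.equals(other.barcode_to_element)
            and self.samples.to_frame().equals(other.samples.to_frame())
            and np.allclose(self.rna_lib_sizes, other.rna_lib_sizes)
            and np.allclose(self.dna_lib_sizes, other.dna_lib_sizes)
        )


# ---------------------------------------------------------------------------
# element-level activity
# ---------------------------------------------------------------------------

@dataclass
class ElementActivityMatrix:
    """Element x sample log2 RNA/DNA activity measures.

    ``estimator`` records how the matrix was produced ("aggregate" or
    "average").  ``mean_log2_dna`` is the across-sample average of
    log2(1 + (L/N_d) * sum_b D_b), the copy-number axis of the
    variance-trend plot; ``obs_log2_dna`` is the same quantity before
    averaging, one value per observation, used to evaluate precision
    weights at each observation's own DNA abundance.
    """

    activity: pd.DataFrame
    estimator: str
    mean_log2_dna: pd.Series
    common_lib_size: float
    obs_log2_dna: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.estimator not in ("aggregate", "average"):
            raise MpraFormatError(f"unknown estimator tag: {self.estimator!r}")

    @property
    def element_ids(self) -> list:
        return list(self.activity.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.activity.columns)

    def subset(self, elements) -> "ElementActivityMatrix":
        return ElementActivityMatrix(
            activity=self.activity.loc[elements],
            estimator=self.estimator,
            mean_log2_dna=self.mean_log2_dna.loc[elements],
            common_lib_size=self.common_lib_size,
            obs_log2_dna=None if self.obs_log2_dna is None else self.obs_log2_dna.loc[elements],
        )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _read_table(path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    frame.index = frame.index.astype(str)
    return frame


def read_counts(rna_path, dna_path, map_path, sample_path) -> BarcodeCountSet:
    """Read RNA/DNA count tables, the barcode->element map and sample sheet.

    All files are tab-separated; count tables have barcode ids in the first
    column and sample ids in the header.  Raises :class:`MpraFormatError`
    on mismatched samples, unmapped barcodes or non-integer counts.
    """
    rna = _read_table(rna_path)
    dna = _read_table(dna_path)
    if list(rna.columns) != list(dna.columns):
        raise MpraFormatError(
            f"rna samples {list(rna.columns)} != dna samples {list(dna.columns)}"
        )
    mapping_frame = pd.read_csv(map_path, sep="\t", comment="#", dtype=str)
    if mapping_frame.shape[1] < 2:
        raise MpraFormatError("element map needs two columns: barcode, element")
    mapping = pd.Series(
        mapping_frame.iloc[:, 1].to_numpy(), index=mapping_frame.iloc[:, 0].astype(str)
    )
    samples = SampleSheet.from_frame(_read_table(sample_path))
    return BarcodeCountSet(
        rna=rna, dna=dna, barcode_to_element=mapping, samples=samples
    )


def write_counts(counts: BarcodeCountSet, rna_path, dna_path, map_path, sample_path) -> None:
    """Write a BarcodeCountSet in the canonical tab-separated dialect."""
    counts.rna.rename_axis("barcode").to_csv(rna_path, sep="\t")
    counts.dna.rename_axis("barcode").to_csv(dna_path, sep="\t")
    pd.DataFrame(
        {"barcode": counts.barcode_to_element.index, "element": counts.barcode_to_element.to_numpy()}
    ).to_csv(map_path, sep="\t", index=False)
    counts.samples.to_frame().to_csv(sample_path, sep="\t")


# ---------------------------------------------------------------------------
# normalization & filtering
# ---------------------------------------------------------------------------

def total_count_normalize(counts: BarcodeCountSet, common_lib_size="mean") -> BarcodeCountSet:
    """Record total-count normalization to a common library size L.

    L defaults to the grand mean of all RNA and DNA library sizes.  The
    returned object carries per-sample scale factors L/N_r and L/N_d; raw
    counts are unchanged and the scaling (and the +1 offset) is applied
    inside the activity estimators.
    """
    if (counts.rna_lib_sizes <= 0).any() or (counts.dna_lib_sizes <= 0).any():
        raise MpraFormatError("library sizes must be strictly positive")
    if common_lib_size == "mean":
        sizes = np.concatenate([counts.rna_lib_sizes, counts.dna_lib_sizes])
        common_lib_size = float(sizes.mean())
    common_lib_size = float(common_lib_size)
    if common_lib_size <= 0:
        raise MpraFormatError("common library size must be positive")
    return replace(counts, common_lib_size=common_lib_size)


@dataclass
class FilterReport:
    """Dropped element ids keyed by reason."""

    low_dna: list = field(default_factory=list)
    constant_ratio: list = field(default_factory=list)

    @property
    def dropped(self) -> list:
        return list(dict.fromkeys(self.low_dna + self.constant_ratio))

    def to_frame(self) -> pd.DataFrame:
        rows = [{"element": e, "reason": "low_dna"} for e in self.low_dna]
        rows += [{"element": e, "reason": "constant_ratio"} for e in self.constant_ratio]
        return pd.DataFrame(rows, columns=["element", "reason"])


def filter_elements(
    activity: ElementActivityMatrix,
    counts: BarcodeCountSet,
    min_dna: int = 10,
) -> tuple[ElementActivityMatrix, FilterReport]:
    """Drop low-count and degenerate elements ahead of modeling.

    An element is dropped when its aggregated (summed over barcodes, raw)
    DNA count is below ``min_dna`` in any sample — low DNA makes the
    log-ratio unstable — or when its log-ratios are identical across all
    samples (in practice: RNA counts all zero), which carries no
    information about variability.
    """
    agg_dna = counts.aggregated("dna").loc[activity.element_ids]
    low = agg_dna.lt(min_dna).any(axis=1)
    values = activity.activity.to_numpy()
    constant = np.ptp(values, axis=1) == 0
    report = FilterReport(
        low_dna=list(agg_dna.index[low]),
        constant_ratio=list(activity.activity.index[constant & ~low.to_numpy()]),
    )
    keep = activity.activity.index[~(low.to_numpy() | constant)]
    if len(keep) == 0:
        warnings.warn("all elements removed by filtering", stacklevel=2)
    return activity.subset(keep), report
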