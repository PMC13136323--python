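"""Raw intensity tables -> normalized log2 matrices.

The normalization contract is fixed: divide each sample by its protein
concentration, log2-transform (zeros/nonpositive values become missing),
then center each sample at its median.  Metabolite exclusions (e.g. the
anesthetic-derived epinephrine signal in muscle biopsies) are applied
before normalization so that excluded rows can never shift a sample
median.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

ANNOTATION_COLUMNS = [
    "sample_id",
    "subject_id",
    "group",
    "tissue",
    "visit_week",
    "protein_conc",
    "quality_flag",
]

MEDIAN_TOL = 1e-9


@dataclass
class MetaboliteMatrix:
    """Raw metabolite-by-sample intensities plus per-sample protein content.

    Parameters
    ----------
    intensities
        DataFrame indexed by metabolite id, columns are sample ids,
        values are nonnegative raw intensities.
    protein_conc
        Protein concentration (mg/mL) per sample, indexed by sample id.
    tissue
        ``"muscle"`` or ``"serum"``.
    audit
        Ordered record of operations applied so far.
    """

    intensities: pd.DataFrame
    protein_conc: pd.Series
    tissue: str = "muscle"
    audit: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.intensities.index.has_duplicates:
            raise ValueError("duplicate metabolite identifiers")
        if self.intensities.columns.has_duplicates:
            raise ValueError("duplicate sample identifiers")
        vals = self.intensities.to_numpy(dtype=float)
        if np.nanmin(vals, initial=0.0) < 0:
            raise ValueError("negative intensities are not allowed")
        prot = self.protein_conc.reindex(self.intensities.columns)
        if prot.isna().any():
            missing = list(prot.index[prot.isna()])
            raise ValueError(f"protein concentration missing for samples {missing}")
        if (prot <= 0).any():
            bad = list(prot.index[prot <= 0])
            raise ValueError(f"nonpositive protein concentration for samples {bad}")
        self.protein_conc = prot.astype(float)

    @property
    def metabolite_ids(self) -> list:
        return list(self.intensities.index)

    @property
    def sample_ids(self) -> list:
        return list(self.intensities.columns)


@dataclass
class NormalizedMatrix:
    """Per-sample median-centered log2 intensities (missing allowed)."""

    log2_values: pd.DataFrame
    tissue: str = "muscle"
    audit: list = field(default_factory=list)

    @property
    def metabolite_ids(self) -> list:
        return list(self.log2_values.index)

    @property
    def sample_ids(self) -> list:
        return list(self.log2_values.columns)


def exclude_metabolites(m: MetaboliteMatrix, exclusion_list) -> MetaboliteMatrix:
    """Drop listed metabolites (idempotent; absent ids raise a warning only)."""
    exclusion = list(exclusion_list)
    present = [x for x in exclusion if x in m.intensities.index]
    absent = [x for x in exclusion if x not in m.intensities.index]
    if absent:
        warnings.warn(f"exclusion list entries not present: {absent}", stacklevel=2)
    out = m.intensities.drop(index=present)
    audit = m.audit + [f"exclude_metabolites: removed {len(present)} of {len(exclusion)} listed"]
    return replace(m, intensities=out, audit=audit)


def normalize(m: MetaboliteMatrix) -> NormalizedMatrix:
    """Protein division -> log2 (nonpositive -> missing) -> median centering."""
    vals = m.intensities.to_numpy(dtype=float)
    prot = m.protein_conc.to_numpy(dtype=float)

    per_protein = vals / prot[np.newaxis, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        log2 = np.where(per_protein > 0, np.log2(np.where(per_protein > 0, per_protein, 1.0)), np.nan)

    n_missing = int(np.isnan(log2).sum())
    all_missing = np.isnan(log2).all(axis=0)
    if all_missing.any():
        bad = list(m.intensities.columns[all_missing])
        raise ValueError(f"sample(s) with no positive intensities, median undefined: {bad}")

    medians = np.nanmedian(log2, axis=0)
    centered = log2 - medians[np.newaxis, :]

    audit = m.audit + [
        "normalize: divided intensities by per-sample protein concentration",
        f"normalize: log2 transform ({n_missing} nonpositive cells set missing)",
        "normalize: centered each sample at its median (target 0)",
    ]
    df = pd.DataFrame(centered, index=m.intensities.index, columns=m.intensities.columns)
    check = np.nanmedian(df.to_numpy(), axis=0)
    assert np.nanmax(np.abs(check)) < MEDIAN_TOL
    return NormalizedMatrix(log2_values=df, tissue=m.tissue, audit=audit)


def intersect_features(a: NormalizedMatrix, b: NormalizedMatrix) -> list:
    """Sorted metabolite ids common to both matrices; errors when empty."""
    common = sorted(set(a.metabolite_ids) & set(b.metabolite_ids))
    if not common:
        raise ValueError("no shared metabolites between matrices")
    return common


# ---------------------------------------------------------------------------
# TSV interchange


def read_intensity_tsv(path, metadata: pd.DataFrame, tissue: str) -> MetaboliteMatrix:
    """Read an intensity table (first column metabolite id) and attach
    protein concentrations from the sample-metadata table."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    meta = metadata.set_index("sample_id")
    missing = [s for s in df.columns if s not in meta.index]
    if missing:
        raise ValueError(f"samples missing from metadata: {missing}")
    prot = meta.loc[df.columns, "protein_conc"].astype(float)
    return MetaboliteMatrix(intensities=df, protein_conc=prot, tissue=tissue)


def read_metadata_tsv(path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t")
    missing = [c for c in ANNOTATION_COLUMNS if c not in meta.columns]
    if missing:
        raise ValueError(f"metadata file lacks columns: {missing}")
    if meta["sample_id"].duplicated().any():
        dup = list(meta.loc[meta["sample_id"].duplicated(), "sample_id"])
        raise ValueError(f"duplicate sample annotations: {dup}")
    return meta


def write_normalized_tsv(x: NormalizedMatrix, path) -> None:
    x.log2_values.to_csv(path, sep="\t", float_format="%.6g", na_rep="")
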