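"""Perturbation dataset model, file I/O, preprocessing filters and labels.

A dataset is a list of treatment instances — one (molecule, cell line) pair
with dose, exposure time, QC flag, transcriptional activity score (TAS) and
a signed differential-expression profile over the landmark genes — plus the
ordered gene / pathway / anchor-cell vocabularies and a basal expression
matrix used for similarity-based cell embeddings.

The on-disk schema is a TSV with fixed metadata columns followed by one
column per gene::

    smiles  cell_id  dose_um  time_h  qc_pass  tas  <gene_1> ... <gene_n>

Pathway gene sets use the standard GMT format (set name, description, then
gene symbols, tab separated).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence
import warnings

import numpy as np
import pandas as pd

__all__ = [
    "PerturbationInstance", "PerturbationDataset", "FilterReport",
    "SchemaError", "read_perturbation_table", "write_perturbation_table",
    "read_gene_sets_gmt", "write_gene_sets_gmt",
    "read_basal_expression", "write_basal_expression",
    "filter_dose_time", "filter_qc", "filter_tas", "filter_accounting",
    "build_pathway_labels", "read_two_column_tsv",
]

METADATA_COLUMNS = ["smiles", "cell_id", "dose_um", "time_h", "qc_pass", "tas"]


class SchemaError(ValueError):
    """Raised when an input file does not match the documented schema."""


@dataclass
class PerturbationInstance:
    """One (molecule, cell line) treatment and its signed DEG profile."""

    molecule_smiles: str
    cell_id: str
    dose: float                      # μM
    time: float                      # hours
    qc_pass: bool
    tas: float                      # transcriptional activity score in [0,1]
    deg_profile: np.ndarray          # signed, length n_genes
    pathway_labels: Optional[np.ndarray] = None   # binary, length n_pathways

    def __post_init__(self):
        self.deg_profile = np.asarray(self.deg_profile, dtype=float)
        if not 0.0 <= self.tas <= 1.0:
            raise ValueError(f"TAS must be in [0,1], got {self.tas}")
        if self.pathway_labels is not None:
            lab = np.asarray(self.pathway_labels)
            if not np.isin(lab, [0, 1]).all():
                raise ValueError("pathway labels must be binary")
            self.pathway_labels = lab.astype(float)


@dataclass
class PerturbationDataset:
    instances: list[PerturbationInstance]
    gene_ids: list[str]
    pathway_ids: list[str] = field(default_factory=list)
    anchor_cell_ids: list[str] = field(default_factory=list)
    basal_expression: Optional[pd.DataFrame] = None   # genes × cells

    def __post_init__(self):
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene ids")
        n = len(self.gene_ids)
        for i, inst in enumerate(self.instances):
            if inst.deg_profile.shape != (n,):
                raise ValueError(
                    f"instance {i}: profile length {inst.deg_profile.shape} "
                    f"!= {n} genes")

    def __len__(self) -> int:
        return len(self.instances)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def subset(self, keep: Iterable[int]) -> "PerturbationDataset":
        keep = list(keep)
        return replace(self, instances=[self.instances[i] for i in keep])

    def profile_matrix(self) -> np.ndarray:
        return np.array([i.deg_profile for i in self.instances])


@dataclass
class FilterReport:
    """Per-stage accounting of a preprocessing cascade."""

    stage_names: list[str]
    counts_before: list[int]
    counts_after: list[int]
    pct_eliminated: list[float]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "stage": self.stage_names,
            "before": self.counts_before,
            "after": self.counts_after,
            "pct_eliminated": self.pct_eliminated,
        })


# --------------------------------------------------------------------- I/O

def read_perturbation_table(path) -> PerturbationDataset:
    """Read the perturbation TSV; gene order is taken from the header."""
    df = pd.read_csv(path, sep="\t", dtype={"smiles": str, "cell_id": str})
    missing = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"perturbation table {path} lacks column(s): "
                          f"{', '.join(missing)}")
    gene_ids = [c for c in df.columns if c not in METADATA_COLUMNS]
    if not gene_ids:
        raise SchemaError(f"perturbation table {path} has no gene columns")
    prof = df[gene_ids].apply(pd.to_numeric, errors="coerce")
    bad = prof.isna().to_numpy() & df[gene_ids].notna().to_numpy()
    if bad.any():
        row = int(np.argwhere(bad)[0][0])
        raise SchemaError(f"non-numeric DEG value at data row {row}")
    profiles = prof.to_numpy(dtype=float)
    instances = []
    for i, row in enumerate(df.itertuples(index=False)):
        instances.append(PerturbationInstance(
            molecule_smiles=row.smiles, cell_id=row.cell_id,
            dose=float(row.dose_um), time=float(row.time_h),
            qc_pass=_parse_bool(row.qc_pass), tas=float(row.tas),
            deg_profile=profiles[i]))
    return PerturbationDataset(instances=instances, gene_ids=gene_ids)


def _parse_bool(v) -> bool:
    if isinstance(v, (bool, np.bool_)):
        return bool(v)
    s = str(v).strip().lower()
    if s in {"true", "1", "yes", "t"}:
        return True
    if s in {"false", "0", "no", "f"}:
        return False
    raise SchemaError(f"cannot parse boolean value {v!r}")


def write_perturbation_table(ds: PerturbationDataset, path) -> None:
    rows = []
    for inst in ds.instances:
        rows.append([inst.molecule_smiles, inst.cell_id, inst.dose, inst.time,
                     inst.qc_pass, inst.tas, *inst.deg_profile])
    df = pd.DataFrame(rows, columns=METADATA_COLUMNS + list(ds.gene_ids))
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_gene_sets_gmt(path, uppercase_symbols: bool = False
                       ) -> dict[str, set[str]]:
    """Read GMT gene sets: name, description, then member gene symbols.

    Symbol matching elsewhere is case-sensitive; pass
    ``uppercase_symbols=True`` to normalize symbols on ingest when mixing
    sources with inconsistent casing.
    """
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise SchemaError(f"{path}:{ln}: GMT line needs at least "
                                  "name, description and one gene")
            genes = fields[2:]
            if uppercase_symbols:
                genes = [g.upper() for g in genes]
            sets[fields[0]] = set(genes)
    return sets


def write_gene_sets_gmt(sets: Mapping[str, Iterable[str]], path) -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, "na", *sorted(genes)]) + "\n")


def read_basal_expression(path) -> pd.DataFrame:
    """Basal (untreated) expression, rows = genes, columns = cell ids."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_basal_expression(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", float_format="%.10g")


def read_two_column_tsv(path) -> list[tuple[str, str]]:
    """Generic two-column map file (drug→target or target→pathway)."""
    pairs = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise SchemaError(f"{path}:{ln}: expected two tab-separated "
                                  "columns")
            pairs.append((fields[0], fields[1]))
    return pairs


# ------------------------------------------------------------------ filters

def filter_dose_time(ds: PerturbationDataset, dose_target: float = 10.0,
                     time_target: float = 24.0) -> PerturbationDataset:
    """Keep instances treated at exactly ``dose_target`` μM for
    ``time_target`` hours (10 μM / 24 h by default)."""
    keep = [i for i, x in enumerate(ds.instances)
            if x.dose == dose_target and x.time == time_target]
    return ds.subset(keep)


def filter_qc(ds: PerturbationDataset) -> PerturbationDataset:
    """Keep instances whose upstream quality control passed."""
    return ds.subset(i for i, x in enumerate(ds.instances) if x.qc_pass)


def filter_tas(ds: PerturbationDataset, threshold: float = 0.2
               ) -> PerturbationDataset:
    """Keep instances with TAS strictly above ``threshold``; signatures with
    TAS not exceeding the threshold are treated as inactive and dropped."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("TAS threshold must be in [0,1]")
    return ds.subset(i for i, x in enumerate(ds.instances) if x.tas > threshold)


def filter_accounting(stages: Sequence[tuple[str, int, int]]) -> FilterReport:
    """Build a :class:`FilterReport` from (name, before, after) triples.

    Elimination percentages are reported on the 0–100 scale rounded to two
    decimals.
    """
    names, befores, afters, pcts = [], [], [], []
    for name, before, after in stages:
        if before <= 0:
            raise ValueError(f"stage {name!r}: count before filtering must be "
                             "positive")
        if after > before or after < 0:
            raise ValueError(f"stage {name!r}: invalid counts {before}→{after}")
        names.append(name)
        befores.append(int(before))
        afters.append(int(after))
        pcts.append(round(100.0 * (before - after) / before, 2))
    return FilterReport(names, befores, afters, pcts)


def preprocess(ds: PerturbationDataset, dose_target: float = 10.0,
               time_target: float = 24.0, tas_threshold: float = 0.2
               ) -> tuple[PerturbationDataset, FilterReport]:
    """Run the full three-stage cascade (dose/time, QC, TAS) with accounting."""
    n0 = len(ds)
    ds1 = filter_dose_time(ds, dose_target, time_target)
    ds2 = filter_qc(ds1)
    ds3 = filter_tas(ds2, tas_threshold)
    report = filter_accounting([
        (f"dose=={dose_target}um & time=={time_target}h", n0, len(ds1)),
        ("quality control", len(ds1), len(ds2)),
        (f"TAS>{tas_threshold}", len(ds2), len(ds3)),
    ]) if n0 else FilterReport([], [], [], [])
    return ds3, report


# ------------------------------------------------------------------- labels

def build_pathway_labels(drug_targets: Iterable[str],
                         target_to_pathway: Iterable[tuple[str, str]],
                         pathway_ids: Sequence[str]) -> np.ndarray:
    """Binary drug–pathway association vector in ``pathway_ids`` order.

    Entry *p* is 1 iff any of the drug's targets maps to pathway *p*.
    Targets pointing at pathways absent from ``pathway_ids`` are ignored
    with a warning.
    """
    index = {p: i for i, p in enumerate(pathway_ids)}
    by_target: dict[str, set[str]] = {}
    for tgt, pw in target_to_pathway:
        by_target.setdefault(tgt, set()).add(pw)
    labels = np.zeros(len(pathway_ids))
    for tgt in drug_targets:
        for pw in by_target.get(tgt, ()):
            if pw not in index:
                warnings.warn(f"target {tgt!r} maps to unknown pathway {pw!r};"
                              " ignored")
                continue
            labels[index[pw]] = 1.0
    return labels
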