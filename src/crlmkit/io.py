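"""Readers and writers for the tabular formats used throughout the toolkit.

Matrices are features x samples TSV with the feature id in the first column.
Missing values are encoded as an empty cell or "NA" (case-insensitive); zeros
are data, never missing.  Normalized matrices carry a ``#scale=log2`` comment
header that is checked on load.  Gene sets use the GMT dialect
(name TAB description TAB member...).
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

LAYERS = ("cnv", "mrna", "protein", "phosphosite")
TISSUES = ("N", "T", "LM")
EVENT_TYPES = ("A3SS", "A5SS", "MXE", "RI", "SE")

#: phosphosite identifier grammar: GENE_[STY]position, e.g. NDRG1_S330
PHOSPHOSITE_RE = re.compile(r"^(?P<gene>.+)_(?P<residue>[STY])(?P<pos>\d+)$")

_MISSING_TOKENS = {"", "na", "nan"}


class ParseError(ValueError):
    """Malformed input file; message carries the offending line number."""


class ValidationError(ValueError):
    """Structurally valid input violating a domain invariant."""


def site_to_gene(site_id: str) -> str:
    """Parent gene of a phosphosite id (``EIF4B_S422`` -> ``EIF4B``)."""
    m = PHOSPHOSITE_RE.match(site_id)
    if m is None:
        raise ValidationError(f"invalid phosphosite id {site_id!r}; expected GENE_[STY]pos")
    return m.group("gene")


# ---------------------------------------------------------------------------
# OmicsMatrix
# ---------------------------------------------------------------------------

@dataclass
class OmicsMatrix:
    """One omics layer as a features x samples matrix of log2-scale values.

    Parameters
    ----------
    layer : {"cnv", "mrna", "protein", "phosphosite"}
    data : pandas.DataFrame
        Rows are feature ids, columns sample ids, NaN encodes missing.
    is_normalized : bool
        True once per-sample median centering has been applied.
    log2_scale : bool
        False only for raw (linear-intensity) matrices.
    """

    layer: str
    data: pd.DataFrame
    is_normalized: bool = False
    log2_scale: bool = True

    def __post_init__(self) -> None:
        if self.layer not in LAYERS:
            raise ValidationError(f"unknown layer {self.layer!r}; expected one of {LAYERS}")
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate feature ids: {dups[:5]}")
        if self.data.columns.has_duplicates:
            dups = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample ids: {dups[:5]}")
        values = self.data.to_numpy(dtype=float, copy=False)
        if np.isinf(values).any():
            raise ValidationError("matrix contains non-finite (inf) values")
        if self.layer == "phosphosite":
            for fid in self.data.index:
                site_to_gene(fid)

    @property
    def feature_ids(self) -> List[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> List[str]:
        return list(self.data.columns)

    @property
    def shape(self):
        return self.data.shape

    def missing_fraction(self) -> float:
        return float(self.data.isna().to_numpy().mean()) if self.data.size else 0.0

    def subset_samples(self, sample_ids: Sequence[str]) -> "OmicsMatrix":
        missing = [s for s in sample_ids if s not in self.data.columns]
        if missing:
            raise ValidationError(f"unknown sample ids: {missing[:5]}")
        return OmicsMatrix(self.layer, self.data.loc[:, list(sample_ids)],
                           self.is_normalized, self.log2_scale)

    def drop_samples(self, sample_ids: Iterable[str]) -> "OmicsMatrix":
        keep = [s for s in self.data.columns if s not in set(sample_ids)]
        return OmicsMatrix(self.layer, self.data.loc[:, keep],
                           self.is_normalized, self.log2_scale)


def _parse_cell(token: str, line_no: int, col: str) -> float:
    token = token.strip()
    if token.lower() in _MISSING_TOKENS:
        return np.nan
    try:
        return float(token)
    except ValueError:
        raise ParseError(
            f"line {line_no}: non-numeric cell {token!r} in column {col!r}") from None


def load_omics_matrix(path, layer: str) -> OmicsMatrix:
    """Load a features x samples TSV as an :class:`OmicsMatrix`.

    Header comments (``#key=value`` lines before the header row) are honoured:
    ``#scale=log2`` marks an already-log2 matrix, ``#normalized=true`` a
    median-centred one.
    """
    meta: Dict[str, str] = {}
    header: Optional[List[str]] = None
    features: List[str] = []
    rows: List[List[float]] = []
    seen: Set[str] = set()
    n_rejected = 0
    with open(path, newline="") as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if header is None and line.startswith("#"):
                if "=" in line:
                    key, _, val = line[1:].partition("=")
                    meta[key.strip()] = val.strip()
                continue
            parts = line.split("\t")
            if header is None:
                header = [p.strip() for p in parts[1:]]
                if len(set(header)) != len(header):
                    raise ParseError(f"line {line_no}: duplicate sample ids in header")
                continue
            if not line.strip():
                continue
            if len(parts) != len(header) + 1:
                raise ParseError(
                    f"line {line_no}: expected {len(header) + 1} fields, got {len(parts)}")
            fid = parts[0].strip()
            if fid in seen:
                raise ParseError(f"line {line_no}: duplicate feature id {fid!r}")
            seen.add(fid)
            features.append(fid)
            rows.append([_parse_cell(tok, line_no, col)
                         for tok, col in zip(parts[1:], header)])
    if header is None:
        raise ParseError("empty file: no header row found")
    data = pd.DataFrame(rows, index=features, columns=header, dtype=float)
    logger.info("loaded %s matrix %s: %d features x %d samples (%d rejected rows)",
                layer, path, len(features), len(header), n_rejected)
    return OmicsMatrix(
        layer=layer,
        data=data,
        is_normalized=meta.get("normalized", "").lower() == "true",
        log2_scale=meta.get("scale", "log2") == "log2",
    )


def write_omics_matrix(m: OmicsMatrix, path) -> None:
    """Serialize with >= 12 significant digits so round trips are bit-exact."""
    with open(path, "w", newline="") as fh:
        if m.log2_scale:
            fh.write("#scale=log2\n")
        fh.write(f"#normalized={'true' if m.is_normalized else 'false'}\n")
        fh.write(f"#layer={m.layer}\n")
        fh.write("feature_id\t" + "\t".join(m.data.columns) + "\n")
        for fid, row in zip(m.data.index, m.data.to_numpy()):
            cells = ["" if np.isnan(v) else repr(float(v)) for v in row]
            fh.write(fid + "\t" + "\t".join(cells) + "\n")


# ---------------------------------------------------------------------------
# Clinical records
# ---------------------------------------------------------------------------

@dataclass
class ClinicalRecord:
    """Per-sample clinical metadata with patient-level survival endpoints."""

    patient_id: str
    sample_id: str
    tissue: str
    os_time: float
    os_event: int
    crs: Optional[int] = None
    subtype: Optional[str] = None
    pfs_time: Optional[float] = None
    pfs_event: Optional[int] = None

    def __post_init__(self) -> None:
        if self.tissue not in TISSUES:
            raise ValidationError(
                f"sample {self.sample_id}: unknown tissue {self.tissue!r}")
        if self.os_time < 0:
            raise ValidationError(f"sample {self.sample_id}: negative os_time")
        if self.os_event not in (0, 1):
            raise ValidationError(f"sample {self.sample_id}: os_event must be 0/1")
        if self.crs is not None and not 0 <= self.crs <= 5:
            raise ValidationError(f"sample {self.sample_id}: CRS must be 0-5")
        if self.subtype is not None and self.subtype not in ("C1", "C2"):
            raise ValidationError(f"sample {self.sample_id}: subtype must be C1/C2")
        if self.pfs_time is not None and self.pfs_time < 0:
            raise ValidationError(f"sample {self.sample_id}: negative pfs_time")


_CLINICAL_REQUIRED = ["patient_id", "sample_id", "tissue", "os_time", "os_event"]


def load_clinical(path) -> List[ClinicalRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in _CLINICAL_REQUIRED if c not in df.columns]
    if missing:
        raise ParseError(f"clinical table missing required columns: {missing}")
    records = []
    for _, row in df.iterrows():
        def opt(col, cast):
            if col not in df.columns:
                return None
            val = row[col]
            if pd.isna(val) or str(val).strip().lower() in _MISSING_TOKENS:
                return None
            return cast(val)

        records.append(ClinicalRecord(
            patient_id=row["patient_id"],
            sample_id=row["sample_id"],
            tissue=row["tissue"],
            os_time=float(row["os_time"]),
            os_event=int(float(row["os_event"])),
            crs=opt("crs", lambda v: int(float(v))),
            subtype=opt("subtype", str),
            pfs_time=opt("pfs_time", float),
            pfs_event=opt("pfs_event", lambda v: int(float(v))),
        ))
    ids = [r.sample_id for r in records]
    if len(set(ids)) != len(ids):
        raise ValidationError("duplicate sample ids in clinical table")
    logger.info("loaded %d clinical records from %s", len(records), path)
    return records


def write_clinical(records: Sequence[ClinicalRecord], path) -> None:
    cols = ["patient_id", "sample_id", "tissue", "crs", "subtype",
            "os_time", "os_event", "pfs_time", "pfs_event"]
    with open(path, "w", newline="") as fh:
        fh.write("\t".join(cols) + "\n")
        for r in records:
            vals = [getattr(r, c) for c in cols]
            fh.write("\t".join("" if v is None else str(v) for v in vals) + "\n")


def clinical_frame(records: Sequence[ClinicalRecord]) -> pd.DataFrame:
    """Clinical records as a DataFrame indexed by sample id."""
    df = pd.DataFrame([r.__dict__ for r in records]).set_index("sample_id", drop=False)
    return df


# ---------------------------------------------------------------------------
# Gene sets (GMT)
# ---------------------------------------------------------------------------

@dataclass
class GeneSetCollection:
    """Named, non-empty gene sets plus their GMT description strings."""

    sets: Dict[str, Set[str]]
    descriptions: Dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise ValidationError(f"gene set {name!r} is empty")

    def __getitem__(self, name: str) -> Set[str]:
        return self.sets[name]

    def __iter__(self):
        return iter(self.sets)

    def __len__(self) -> int:
        return len(self.sets)


def load_gene_sets(path) -> GeneSetCollection:
    sets: Dict[str, Set[str]] = {}
    descriptions: Dict[str, str] = {}
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(
                    f"line {line_no}: GMT line needs >= 3 fields (name, description, members)")
            name, desc, *members = parts
            members = [m.strip() for m in members if m.strip()]
            if not members:
                raise ParseError(f"line {line_no}: gene set {name!r} has no members")
            if name in sets:
                raise ParseError(f"line {line_no}: duplicate set name {name!r}")
            sets[name] = set(members)
            descriptions[name] = desc
    return GeneSetCollection(sets, descriptions)


def write_gene_sets(collection: GeneSetCollection, path) -> None:
    with open(path, "w", newline="") as fh:
        for name in collection:
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc] + sorted(collection[name])) + "\n")


# ---------------------------------------------------------------------------
# Kinase-substrate map
# ---------------------------------------------------------------------------

@dataclass
class KinaseSubstrateMap:
    """Kinase id -> set of phosphosite ids (GENE_[STY]pos grammar)."""

    substrates: Dict[str, Set[str]]

    def __post_init__(self) -> None:
        for kinase, sites in self.substrates.items():
            if not sites:
                raise ValidationError(f"kinase {kinase!r} has an empty substrate set")
            for s in sites:
                site_to_gene(s)

    def __getitem__(self, kinase: str) -> Set[str]:
        return self.substrates[kinase]

    def __iter__(self):
        return iter(self.substrates)

    def __len__(self) -> int:
        return len(self.substrates)


def load_kinase_substrate_map(path) -> KinaseSubstrateMap:
    """Two-column TSV (kinase TAB phosphosite), one relation per line."""
    substrates: Dict[str, Set[str]] = {}
    with open(path) as fh:
        reader = csv.reader(fh, delimiter="\t")
        for line_no, parts in enumerate(reader, start=1):
            if not parts or not "".join(parts).strip():
                continue
            if parts[0].lower() in ("kinase", "#kinase"):
                continue
            if len(parts) < 2:
                raise ParseError(f"line {line_no}: expected kinase TAB site")
            substrates.setdefault(parts[0].strip(), set()).add(parts[1].strip())
    return KinaseSubstrateMap(substrates)


def write_kinase_substrate_map(ksmap: KinaseSubstrateMap, path) -> None:
    with open(path, "w", newline="") as fh:
        fh.write("kinase\tsite\n")
        for kinase in sorted(ksmap.substrates):
            for site in sorted(ksmap[kinase]):
                fh.write(f"{kinase}\t{site}\n")


# ---------------------------------------------------------------------------
# Alternative-splicing event table (rMATS-like)
# ---------------------------------------------------------------------------

_AS_FIXED_COLS = ["event_id", "gene", "event_type", "inc_level_difference", "fdr"]


@dataclass
class ASEventTable:
    """rMATS-style table: per-event PSI across samples plus summary columns.

    ``events`` holds the fixed columns indexed by event id; ``psi`` is an
    events x samples matrix of percent-spliced-in values in [0, 1].
    """

    events: pd.DataFrame
    psi: pd.DataFrame

    def __post_init__(self) -> None:
        if self.events.index.has_duplicates:
            raise ValidationError("duplicate AS event ids")
        if not self.events.index.equals(self.psi.index):
            raise ValidationError("event and PSI tables disagree on event ids")
        bad_type = set(self.events["event_type"]) - set(EVENT_TYPES)
        if bad_type:
            raise ValidationError(f"unknown AS event types: {sorted(bad_type)}")
        vals = self.psi.to_numpy(dtype=float)
        finite = vals[np.isfinite(vals)]
        if finite.size and (finite.min() < 0 or finite.max() > 1):
            raise ValidationError("PSI values must lie in [0, 1]")
        ild = self.events["inc_level_difference"].to_numpy(dtype=float)
        if np.any(np.abs(ild[np.isfinite(ild)]) > 1):
            raise ValidationError("inc_level_difference must lie in [-1, 1]")
        fdr = self.events["fdr"].to_numpy(dtype=float)
        if np.any((fdr[np.isfinite(fdr)] < 0) | (fdr[np.isfinite(fdr)] > 1)):
            raise ValidationError("fdr must lie in [0, 1]")

    @property
    def event_ids(self) -> List[str]:
        return list(self.events.index)

    @property
    def sample_ids(self) -> List[str]:
        return list(self.psi.columns)


def load_as_events(path) -> ASEventTable:
    df = pd.read_csv(path, sep="\t", dtype={"event_id": str, "gene": str,
                                            "event_type": str})
    missing = [c for c in _AS_FIXED_COLS if c not in df.columns]
    if missing:
        raise ParseError(f"AS table missing required columns: {missing}")
    df = df.set_index("event_id")
    psi_cols = [c for c in df.columns if c not in _AS_FIXED_COLS]
    events = df[[c for c in _AS_FIXED_COLS if c != "event_id"]]
    psi = df[psi_cols].astype(float)
    return ASEventTable(events=events, psi=psi)


def write_as_events(table: ASEventTable, path) -> None:
    out = table.events.join(table.psi)
    out.index.name = "event_id"
    out.to_csv(path, sep="\t", na_rep="NA")


# ---------------------------------------------------------------------------
# Phosphosite annotations
# ---------------------------------------------------------------------------

@dataclass
class SiteAnnotation:
    """Per-site functional score in [0, 1] and localization class (I / II)."""

    table: pd.DataFrame  # index: site id; columns: functional_score, localization_class

    def __post_init__(self) -> None:
        if self.table.index.has_duplicates:
            raise ValidationError("duplicate site ids in annotation")
        scores = self.table["functional_score"].to_numpy(dtype=float)
        finite = scores[np.isfinite(scores)]
        if np.any((finite < 0) | (finite > 1)):
            raise ValidationError("functional scores must lie in [0, 1]")
        bad = set(self.table["localization_class"].dropna()) - {"I", "II"}
        if bad:
            raise ValidationError(f"unknown localization classes: {sorted(bad)}")
        for sid in self.table.index:
            site_to_gene(sid)

    def functional_score(self, site_id: str) -> Optional[float]:
        if site_id not in self.table.index:
            return None
        val = self.table.at[site_id, "functional_score"]
        return None if pd.isna(val) else float(val)

    def localization_class(self, site_id: str) -> Optional[str]:
        if site_id not in self.table.index:
            return None
        val = self.table.at[site_id, "localization_class"]
        return None if pd.isna(val) else str(val)


def load_site_annotation(path) -> SiteAnnotation:
    df = pd.read_csv(path, sep="\t", dtype={"site": str, "localization_class": str})
    for col in ("site", "functional_score", "localization_class"):
        if col not in df.columns:
            raise ParseError(f"site annotation missing column {col!r}")
    return SiteAnnotation(df.set_index("site"))


def write_site_annotation(ann: SiteAnnotation, path) -> None:
    out = ann.table.copy()
    out.index.name = "site"
    out.to_csv(path, sep="\t", na_rep="NA")


# ---------------------------------------------------------------------------
# Binary mutation matrix (minimal gene x sample TSV)
# ---------------------------------------------------------------------------

def load_mutation_matrix(path) -> pd.DataFrame:
    """Gene x sample binary (0/1) mutation indicator matrix."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    vals = df.to_numpy()
    if not np.isin(vals[~pd.isna(vals)], (0, 1)).all():
        raise ValidationError("mutation matrix must be binary 0/1")
    return df.astype(float)


def write_mutation_matrix(df: pd.DataFrame, path) -> None:
    out = df.copy()
    out.index.name = "gene"
    out.to_csv(path, sep="\t", na_rep="NA")
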