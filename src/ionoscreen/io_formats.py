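"""Readers and writers for every external table the screen pipeline touches.

The plate table is the package's canonical ingest format: one row per well,
metadata columns plus one concentration column (ppm) per element of the
panel.  Z tables follow the layout of published per-gene moderated-Z
supplements (gene id, optional gene name, one column per element, with "-"
or blank marking a non-reported cell).  Interaction tables are BioGRID TAB
2.0/3.0.  Ontology (OBO 1.2) and annotation (GAF 2.x) parsing primitives
live here and are consumed by :mod:`ionoscreen.enrichment`.
"""
from __future__ import annotations

import csv
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import networkx as nx
import numpy as np
import pandas as pd

from .errors import FormatError, ParseError, SchemaError, ValidationError

__all__ = [
    "ElementPanel",
    "WellRecord",
    "RawScreenSet",
    "ZRecord",
    "InteractionRecord",
    "read_plate_table",
    "write_plate_table",
    "read_ztable",
    "ztable_to_frame",
    "read_biogrid_tab",
    "write_results",
    "read_results",
    "read_obo",
    "read_gaf",
    "CONTROL",
    "MUTANT",
]

CONTROL = "control"
MUTANT = "mutant"

#: metadata columns of the canonical plate CSV, in canonical order
PLATE_META_COLUMNS = (
    "plate_id",
    "run_id",
    "well",
    "strain_id",
    "role",
    "replicate",
    "od600",
)

_WELL_RE = re.compile(r"^[A-H](?:[1-9]|1[0-2])$")

_KO_ELEMENTS = (
    "Ca", "Cd", "Co", "Cu", "Fe", "K", "Mg",
    "Mn", "Mo", "Na", "Ni", "P", "S", "Zn",
)
_OE_ELEMENTS = _KO_ELEMENTS + ("As", "Cl", "Se")


@dataclass(frozen=True)
class ElementPanel:
    """An ordered set of element symbols quantified by the instrument."""

    names: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.names:
            raise ValidationError("element panel must be non-empty")
        if len(set(self.names)) != len(self.names):
            raise ValidationError("element panel contains duplicate symbols")
        object.__setattr__(self, "names", tuple(self.names))

    @classmethod
    def knockout(cls) -> "ElementPanel":
        """14-element panel used for the deletion (KO/KOd) collections."""
        return cls(_KO_ELEMENTS)

    @classmethod
    def overexpression(cls) -> "ElementPanel":
        """17-element panel (adds As, Cl, Se) used for the OE collection."""
        return cls(_OE_ELEMENTS)

    @classmethod
    def preset(cls, name: str) -> "ElementPanel":
        name = name.upper()
        if name in ("KO", "KOD", "KNOCKOUT"):
            return cls.knockout()
        if name in ("OE", "OVEREXPRESSION"):
            return cls.overexpression()
        raise ValidationError(f"unknown panel preset: {name!r}")

    def __len__(self) -> int:
        return len(self.names)

    def __iter__(self) -> Iterator[str]:
        return iter(self.names)

    def __contains__(self, item: object) -> bool:
        return item in self.names


@dataclass
class WellRecord:
    """One well of a 96-well screen plate."""

    plate_id: str
    run_id: str
    well: str
    strain_id: str
    role: str
    replicate: int
    od600: float
    conc: dict[str, float]

    def validate(self, panel: ElementPanel) -> None:
        if not _WELL_RE.match(self.well):
            raise ValidationError(f"invalid 96-well position: {self.well!r}")
        if self.role not in (CONTROL, MUTANT):
            raise ValidationError(f"unknown strain role: {self.role!r}")
        if self.replicate < 1:
            raise ValidationError(f"replicate index must be >= 1, got {self.replicate}")
        if not self.od600 > 0:
            raise ValidationError(
                f"od600 must be positive in well {self.well} "
                f"of plate {self.plate_id} (got {self.od600})"
            )
        if set(self.conc) != set(panel.names):
            raise ValidationError(
                f"concentration keys do not match the panel in well {self.well}"
            )


@dataclass
class RawScreenSet:
    """All wells of a screen, one row per well, one column per element."""

    data: pd.DataFrame
    panel: ElementPanel

    def __post_init__(self) -> None:
        missing = [c for c in PLATE_META_COLUMNS if c not in self.data.columns]
        missing += [e for e in self.panel if e not in self.data.columns]
        if missing:
            raise SchemaError(f"screen table missing column(s): {', '.join(missing)}")

    @property
    def n_wells(self) -> int:
        return len(self.data)

    def records(self) -> Iterator[WellRecord]:
        for _, row in self.data.iterrows():
            yield WellRecord(
                plate_id=str(row["plate_id"]),
                run_id=str(row["run_id"]),
                well=str(row["well"]),
                strain_id=str(row["strain_id"]),
                role=str(row["role"]),
                replicate=int(row["replicate"]),
                od600=float(row["od600"]),
                conc={e: float(row[e]) for e in self.panel},
            )

    def copy(self) -> "RawScreenSet":
        return RawScreenSet(self.data.copy(), self.panel)


@dataclass
class ZRecord:
    """Per-gene moderated-Z profile; absent cells are simply missing keys."""

    gene_id: str
    gene_name: str | None = None
    z: dict[str, float] = field(default_factory=dict)


@dataclass(frozen=True, order=True)
class InteractionRecord:
    """One undirected typed interaction; endpoints stored in canonical order."""

    gene_a: str
    gene_b: str
    itype: str  # "physical" or "genetic"

    @classmethod
    def make(cls, a: str, b: str, itype: str) -> "InteractionRecord":
        if itype not in ("physical", "genetic"):
            raise ValidationError(f"unknown interaction type: {itype!r}")
        lo, hi = sorted((a, b))
        return cls(lo, hi, itype)


def _canonical_headers(columns: Iterable[str], panel: ElementPanel) -> dict[str, str]:
    """Map actual CSV headers to canonical names, case-insensitively."""
    wanted = {c.lower(): c for c in PLATE_META_COLUMNS}
    wanted.update({e.lower(): e for e in panel})
    out = {}
    for col in columns:
        key = col.strip().lower()
        if key in wanted:
            out[col] = wanted[key]
    return out


def read_plate_table(path: str | Path, panel: ElementPanel) -> RawScreenSet:
    """Read a per-well plate CSV into a validated :class:`RawScreenSet`.

    Header matching is case-insensitive; column order is free.  Rows with a
    missing mandatory field are rejected with a warning.  A missing column
    raises :class:`SchemaError` naming the column; a non-numeric
    concentration raises :class:`ParseError` with the 1-based data row
    number; a non-positive OD raises :class:`ValidationError` naming the
    well.
    """
    df = pd.read_csv(path, dtype=str, skipinitialspace=True)
    rename = _canonical_headers(df.columns, panel)
    df = df.rename(columns=rename)

    missing = [c for c in PLATE_META_COLUMNS if c not in df.columns]
    missing += [e for e in panel if e not in df.columns]
    if missing:
        raise SchemaError(f"plate table missing column(s): {', '.join(missing)}")

    df = df[list(PLATE_META_COLUMNS) + list(panel.names)]

    mandatory_blank = df[list(PLATE_META_COLUMNS)].isna().any(axis=1)
    if mandatory_blank.any():
        bad = (df.index[mandatory_blank] + 2).tolist()  # +2: header + 1-based
        warnings.warn(
            f"rejected {mandatory_blank.sum()} row(s) with missing mandatory "
            f"fields (file lines {bad})",
            stacklevel=2,
        )
        df = df[~mandatory_blank]

    numeric_cols = ["replicate", "od600", *panel.names]
    for col in numeric_cols:
        parsed = pd.to_numeric(df[col], errors="coerce")
        bad = parsed.isna() & df[col].notna()
        if bad.any():
            row = int(df.index[bad][0]) + 2
            raise ParseError(
                f"non-numeric value {df.loc[df.index[bad][0], col]!r} in column "
                f"{col!r} at file line {row}"
            )
        df[col] = parsed

    df = df.reset_index(drop=True)
    df["replicate"] = df["replicate"].astype(int)

    raw = RawScreenSet(df, panel)
    for rec in raw.records():
        rec.validate(panel)
    return raw


def write_plate_table(raw: RawScreenSet, path: str | Path) -> None:
    """Write a :class:`RawScreenSet` back to the canonical plate CSV."""
    cols = list(PLATE_META_COLUMNS) + list(raw.panel.names)
    raw.data[cols].to_csv(path, index=False, float_format="%.10g")


def read_ztable(path: str | Path, panel: ElementPanel) -> list[ZRecord]:
    """Read a gene x element moderated-Z table.

    Accepts any layout with a ``gene_id`` column, an optional ``gene_name``
    column and one column per panel element (matched case-insensitively).
    Blank cells and ``-`` both mean "not reported".
    """
    df = pd.read_csv(path, dtype=str, skipinitialspace=True)
    rename = {}
    for col in df.columns:
        key = col.strip().lower()
        if key in ("gene_id", "orf", "systematic_name"):
            rename[col] = "gene_id"
        elif key in ("gene_name", "gene", "standard_name"):
            rename[col] = "gene_name"
        else:
            for e in panel:
                if key == e.lower():
                    rename[col] = e
    df = df.rename(columns=rename)
    if "gene_id" not in df.columns:
        raise SchemaError("Z table missing column(s): gene_id")

    dupes = df["gene_id"][df["gene_id"].duplicated()].unique().tolist()
    if dupes:
        raise ValidationError(f"duplicate gene_id(s) in Z table: {', '.join(dupes)}")

    records = []
    elements = [e for e in panel if e in df.columns]
    for _, row in df.iterrows():
        z = {}
        for e in elements:
            cell = row[e]
            if cell is None or (isinstance(cell, float) and np.isnan(cell)):
                continue
            cell = str(cell).strip()
            if cell in ("", "-"):
                continue
            # tolerate the unicode minus used in typeset tables
            cell = cell.replace("−", "-")
            try:
                z[e] = float(cell)
            except ValueError as exc:
                raise ParseError(
                    f"non-numeric Z value {cell!r} for gene "
                    f"{row['gene_id']!r}, element {e}"
                ) from exc
        name = row.get("gene_name")
        if isinstance(name, float) and np.isnan(name):
            name = None
        records.append(ZRecord(gene_id=str(row["gene_id"]), gene_name=name, z=z))
    return records


def ztable_to_frame(records: list[ZRecord], panel: ElementPanel) -> pd.DataFrame:
    """Stack ZRecords into a gene x element frame; absent cells become NaN."""
    idx = [r.gene_id for r in records]
    out = pd.DataFrame(np.nan, index=idx, columns=list(panel.names))
    for r in records:
        for e, v in r.z.items():
            out.loc[r.gene_id, e] = v
    return out


# BioGRID TAB layouts: column indices shared by TAB 2.0 (24 cols) and
# TAB 3.0 (37 cols).
_BIOGRID_NCOLS = {24: "tab2", 37: "tab3"}
_COL_SYS_A, _COL_SYS_B = 5, 6
_COL_SYM_A, _COL_SYM_B = 7, 8
_COL_SYSTEM_TYPE = 12
_COL_ORG_A, _COL_ORG_B = 15, 16


def read_biogrid_tab(
    path: str | Path, organism_filter: str | int | None = None
) -> list[InteractionRecord]:
    """Read BioGRID TAB 2.0/3.0 into deduplicated interaction records.

    Self-loops are dropped and each (unordered pair, interaction type) is
    kept once.  Systematic ORF names are preferred as identifiers; rows
    lacking one fall back to the official symbol with a warning.
    """
    records: dict[InteractionRecord, None] = {}
    n_fallback = 0
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        for line_no, row in enumerate(reader, start=1):
            if not row or row[0].startswith("#"):
                continue
            if len(row) not in _BIOGRID_NCOLS:
                raise FormatError(
                    f"unrecognized BioGRID TAB layout: {len(row)} columns at "
                    f"line {line_no} (expected 24 for TAB 2.0 or 37 for TAB 3.0)"
                )
            if organism_filter is not None:
                org = str(organism_filter)
                if row[_COL_ORG_A] != org or row[_COL_ORG_B] != org:
                    continue
            itype = row[_COL_SYSTEM_TYPE].strip().lower()
            if itype not in ("physical", "genetic"):
                continue
            a = row[_COL_SYS_A].strip()
            b = row[_COL_SYS_B].strip()
            if a in ("", "-"):
                a = row[_COL_SYM_A].strip()
                n_fallback += 1
            if b in ("", "-"):
                b = row[_COL_SYM_B].strip()
                n_fallback += 1
            if not a or not b or a == b:
                continue
            records[InteractionRecord.make(a, b, itype)] = None
    if n_fallback:
        warnings.warn(
            f"{n_fallback} interactor(s) lacked a systematic name; "
            "official symbols used instead",
            stacklevel=2,
        )
    return list(records)


def write_results(callset, clusterset, path_prefix: str | Path) -> dict[str, Path]:
    """Write the significance calls and cluster membership CSVs.

    ``<prefix>calls.csv`` has one row per significant (gene, element) cell
    with Z, q, perCh, sign, annealing flag and the gene's effect-size group;
    ``<prefix>clusters.csv`` has one row per clustered gene with its cluster
    id, pattern key and the cluster's median Z profile.  Values round-trip
    through :func:`read_results` to 6+ significant digits.
    """
    prefix = str(path_prefix)
    calls_path = Path(prefix + "calls.csv")
    clusters_path = Path(prefix + "clusters.csv")

    rows = []
    for gene in callset.sign.index:
        for element in callset.sign.columns:
            s = int(callset.sign.loc[gene, element])
            if s == 0:
                continue
            rows.append(
                {
                    "gene_id": gene,
                    "element": element,
                    "z": callset.z.loc[gene, element],
                    "q": callset.q.loc[gene, element],
                    "perCh": (
                        callset.perCh.loc[gene, element]
                        if callset.perCh is not None
                        else np.nan
                    ),
                    "sign": s,
                    "annealing_pass": bool(callset.annealing_pass.loc[gene, element]),
                    "group": (
                        callset.group.get(gene, "") if callset.group is not None else ""
                    ),
                }
            )
    calls_cols = ["gene_id", "element", "z", "q", "perCh", "sign",
                  "annealing_pass", "group"]
    pd.DataFrame(rows, columns=calls_cols).to_csv(
        calls_path, index=False, float_format="%.10g"
    )

    elements = list(clusterset.panel.names)
    crows = []
    for cl in clusterset.clusters:
        key = pattern_key_str(cl.pattern)
        for gene in cl.members:
            row = {"gene_id": gene, "cluster_id": cl.cluster_id, "pattern_key": key}
            if cl.median_profile is not None:
                for e in elements:
                    row[f"median_{e}"] = cl.median_profile[e]
            crows.append(row)
    ccols = ["gene_id", "cluster_id", "pattern_key"] + [f"median_{e}" for e in elements]
    cdf = pd.DataFrame(crows, columns=ccols)
    cdf.to_csv(clusters_path, index=False, float_format="%.10g")
    return {"calls": calls_path, "clusters": clusters_path}


def read_results(path_prefix: str | Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Re-read the CSVs written by :func:`write_results`."""
    prefix = str(path_prefix)
    calls = pd.read_csv(prefix + "calls.csv")
    # pattern keys such as "+0" must stay strings, not parse as numbers
    clusters = pd.read_csv(prefix + "clusters.csv", dtype={"pattern_key": str})
    return calls, clusters


def pattern_key_str(pattern: tuple[int, ...]) -> str:
    """Serialize a sign pattern as e.g. ``+0-0``: one glyph per element."""
    glyph = {1: "+", 0: "0", -1: "-"}
    return "".join(glyph[int(s)] for s in pattern)


def parse_pattern_key(key: str) -> tuple[int, ...]:
    glyph = {"+": 1, "0": 0, "-": -1}
    try:
        return tuple(glyph[c] for c in key)
    except KeyError as exc:
        raise ValidationError(f"invalid pattern key: {key!r}") from exc


def read_obo(path: str | Path) -> "nx.MultiDiGraph":
    """Read an OBO 1.2 ontology into a child->parent multidigraph.

    Thin wrapper over :func:`obonet.read_obo`; edge keys are relation types
    (``is_a``, ``part_of``, ...).  Downstream code filters relations.
    """
    import obonet

    return obonet.read_obo(str(path))


#: GAF 2.x column names (17 columns)
GAF_COLUMNS = (
    "db", "db_object_id", "db_object_symbol", "qualifier", "go_id",
    "db_reference", "evidence_code", "with_from", "aspect",
    "db_object_name", "db_object_synonym", "db_object_type",
    "taxon", "date", "assigned_by", "annotation_extension",
    "gene_product_form_id",
)


def read_gaf(path: str | Path) -> pd.DataFrame:
    """Read a GAF 2.x annotation file (``!`` comment lines skipped).

    Returns a frame with the 17 standard columns; rows whose qualifier
    contains NOT are dropped (negative annotations must not propagate).
    """
    df = pd.read_csv(
        path,
        sep="\t",
        comment="!",
        header=None,
        names=list(GAF_COLUMNS),
        dtype=str,
        keep_default_na=False,
    )
    if df.shape[1] != len(GAF_COLUMNS):
        raise FormatError(
            f"GAF file has {df.shape[1]} columns; expected {len(GAF_COLUMNS)}"
        )
    neg = df["qualifier"].str.contains("NOT", na=False)
    return df[~neg].reset_index(drop=True)
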