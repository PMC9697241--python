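"""Readers and writers for the table dialects the pipeline consumes.

All inputs are plain tab-separated text with a header line.  The dialects are
deliberately minimal named-column conventions (documented in the README);
extra columns are accepted silently so that database version churn does not
break the pipeline.  Every reader validates into the containers of
:mod:`phosphonet.types`; skipped rows are counted and logged so that
``records + skips == input rows`` always holds.
"""
from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Mapping, Union

import pandas as pd

from .types import (
    HomologyTable,
    InteractionTable,
    KinaseTargetMap,
    PhosphoSite,
    ProteinRecord,
    TimeCourseTable,
)

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]


class FormatError(ValueError):
    """A file-level problem: missing mandatory column, wrong shape."""


class RowError(ValueError):
    """A row-level problem; carries the 1-based line number."""

    def __init__(self, line: int, message: str):
        super().__init__(f"line {line}: {message}")
        self.line = line


def _read_tsv(path: PathLike, required: Iterable[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing mandatory column(s) {missing}")
    return df


def read_phospho_sites(path: PathLike, species: str) -> list[ProteinRecord]:
    """Read an EPSD-style phospho-site table (accession, position, residue).

    Duplicate (accession, position) rows collapse to a single site; site
    counts therefore equal the number of distinct positions per accession.
    Lengths and masses are unknown at this stage (``None``).
    """
    df = _read_tsv(path, ["accession", "position", "residue"])
    sites: dict[str, dict[int, str]] = {}
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            pos = int(getattr(row, "position"))
        except ValueError:
            raise RowError(i, f"non-integer position {getattr(row, 'position')!r}")
        if pos < 1:
            raise RowError(i, f"position must be >= 1, got {pos}")
        residue = str(getattr(row, "residue")).upper()
        sites.setdefault(getattr(row, "accession"), {})[pos] = residue
    return [
        ProteinRecord(
            accession=acc,
            species=species,
            phospho_sites=tuple(
                PhosphoSite(p, r) for p, r in sorted(by_pos.items())
            ),
        )
        for acc, by_pos in sites.items()
    ]


def read_protein_table(path: PathLike, species: str) -> list[ProteinRecord]:
    """Read a UniProt-style protein table (accession, length, mass)."""
    df = _read_tsv(path, ["accession", "length", "mass"])
    out: list[ProteinRecord] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            length = int(getattr(row, "length"))
            mass = float(getattr(row, "mass"))
        except ValueError as exc:
            raise RowError(i, str(exc))
        if length <= 0:
            raise RowError(i, f"non-positive length {length}")
        if mass <= 0:
            raise RowError(i, f"non-positive mass {mass}")
        out.append(
            ProteinRecord(
                accession=getattr(row, "accession"),
                species=species,
                length=length,
                mass=mass,
            )
        )
    return out


def merge_records(
    sites: list[ProteinRecord], table: list[ProteinRecord]
) -> list[ProteinRecord]:
    """Attach phospho-sites to the reference protein table.

    The protein table defines the proteome: proteins absent from the site
    table get an empty site list; site-table entries with no reference record
    are dropped (they carry no length/mass and cannot enter density or
    regression statistics) with a logged count.
    """
    by_acc = {r.accession: r for r in sites}
    merged: list[ProteinRecord] = []
    used: set[str] = set()
    for rec in table:
        hit = by_acc.get(rec.accession)
        if hit is not None:
            used.add(rec.accession)
        merged.append(
            ProteinRecord(
                accession=rec.accession,
                species=rec.species,
                length=rec.length,
                mass=rec.mass,
                phospho_sites=hit.phospho_sites if hit is not None else (),
                homology_group=rec.homology_group,
            )
        )
    dropped = len(by_acc) - len(used)
    if dropped:
        logger.warning(
            "%d phospho-site entries had no reference protein and were dropped",
            dropped,
        )
    return merged


def read_homologene(
    path: PathLike, taxid_map: Mapping[int, str]
) -> HomologyTable:
    """Read a HomoloGene 6-column flat file.

    Columns: HID, taxid, gene id, gene symbol, protein gi, protein accession
    (no header).  Taxids not present in ``taxid_map`` are skipped with a
    logged count.
    """
    groups: dict[int, dict[str, list[str]]] = {}
    skipped = 0
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 6:
                raise RowError(i, f"expected 6 columns, got {len(parts)}")
            try:
                hid = int(parts[0])
                taxid = int(parts[1])
            except ValueError as exc:
                raise RowError(i, str(exc))
            species = taxid_map.get(taxid)
            if species is None:
                skipped += 1
                continue
            groups.setdefault(hid, {}).setdefault(species, []).append(parts[5])
    if skipped:
        logger.warning("%d HomoloGene lines with unmapped taxids skipped", skipped)
    return HomologyTable(groups=groups)


def attach_homology(
    records: list[ProteinRecord], homology: HomologyTable
) -> list[ProteinRecord]:
    """Return records with ``homology_group`` filled in from the table."""
    hid_of = homology.hid_of()
    return [
        ProteinRecord(
            accession=r.accession,
            species=r.species,
            length=r.length,
            mass=r.mass,
            phospho_sites=r.phospho_sites,
            homology_group=hid_of.get(r.accession),
        )
        for r in records
    ]


def read_interactions(path: PathLike) -> InteractionTable:
    """Read a STRING-style interaction table (protein1, protein2, combined_score).

    The score dialect is auto-detected: any value above 1 implies the 0-999
    integer scale, which is divided by 1000 on read.  Duplicate and reversed
    pairs collapse keeping the maximum score; self-loops are dropped with a
    logged count.
    """
    df = pd.read_csv(path, sep=None, engine="python", dtype=str)
    required = ["protein1", "protein2", "combined_score"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing mandatory column(s) {missing}")
    try:
        scores = df["combined_score"].astype(float)
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric combined_score ({exc})")
    integer_scale = bool((scores > 1.0).any())
    table = InteractionTable(score_scale="0-999" if integer_scale else "unit")
    self_loops = 0
    for i, row in enumerate(df.itertuples(index=False), start=2):
        a = getattr(row, "protein1")
        b = getattr(row, "protein2")
        raw = float(getattr(row, "combined_score"))
        if integer_scale:
            if not 0 <= raw <= 999:
                raise RowError(i, f"score {raw} outside 0-999 dialect")
            score = raw / 1000.0
        else:
            if not 0.0 <= raw <= 1.0:
                raise RowError(i, f"score {raw} outside [0, 1] dialect")
            score = raw
        if a == b:
            self_loops += 1
            continue
        table.add(a, b, score)
    if self_loops:
        logger.warning("%d self-loop interaction rows dropped", self_loops)
    return table


def read_kinase_targets(path: PathLike) -> KinaseTargetMap:
    """Read a 2-column TSV mapping kinase group name -> target accession."""
    df = _read_tsv(path, ["group", "accession"])
    groups: dict[str, set[str]] = {}
    for row in df.itertuples(index=False):
        groups.setdefault(getattr(row, "group"), set()).add(
            getattr(row, "accession")
        )
    return KinaseTargetMap(
        groups={name: frozenset(t) for name, t in groups.items()}
    )


def read_timecourse(
    path: PathLike, time_points: Iterable[int] = (1, 5, 10, 15, 20, 30)
) -> TimeCourseTable:
    """Read a qPhos-style SILAC time-course table.

    Columns: accession, position, time (minutes), log2fc.  Time points must
    come from the declared ordered list (EGF series default: 1, 5, 10, 15,
    20, 30 min).
    """
    df = _read_tsv(path, ["accession", "position", "time", "log2fc"])
    try:
        out = pd.DataFrame(
            {
                "accession": df["accession"],
                "position": df["position"].astype(int),
                "time": df["time"].astype(int),
                "log2fc": df["log2fc"].astype(float),
            }
        )
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}")
    return TimeCourseTable(records=out, time_points=list(time_points))


def write_table(result: pd.DataFrame, path: PathLike) -> None:
    """Write a result table as TSV with header, full-precision numbers."""
    result.to_csv(path, sep="\t", index=False)


def write_interactions(table: InteractionTable, path: PathLike) -> None:
    rows = [
        {"protein1": a, "protein2": b, "combined_score": s}
        for (a, b), s in sorted(table.edges.items())
    ]
    write_table(pd.DataFrame(rows, columns=["protein1", "protein2", "combined_score"]), path)


def write_protein_records(records: list[ProteinRecord], sites_path: PathLike,
                          proteins_path: PathLike) -> None:
    """Write records back out in the site-table and protein-table dialects."""
    site_rows = [
        {"accession": r.accession, "position": s.position, "residue": s.residue}
        for r in records
        for s in r.phospho_sites
    ]
    write_table(
        pd.DataFrame(site_rows, columns=["accession", "position", "residue"]),
        sites_path,
    )
    prot_rows = [
        {"accession": r.accession, "length": r.length, "mass": r.mass}
        for r in records
        if r.length is not None
    ]
    write_table(
        pd.DataFrame(prot_rows, columns=["accession", "length", "mass"]),
        proteins_path,
    )
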