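"""Reading and writing NanoString nCounter RCC files and cohort assembly.

The RCC dialect handled here is the plain-text nCounter export: sections are
delimited by ``<Tag>`` / ``</Tag>`` lines and the ``Code_Summary`` section is
comma-separated with header ``CodeClass,Name,Accession,Count``.  Four probe
classes are recognised: Endogenous, Housekeeping, Negative (background
controls) and Positive (titration-ladder controls).  Study-level sample
metadata (disease subtype, cartridge, conservation method, patient pairing)
is intentionally *not* read from RCC free-text attributes; it lives in a
separate tab-separated sample sheet.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import RCCFormatError, RCCParseError, ValidationError

CODE_CLASSES = ("Endogenous", "Housekeeping", "Negative", "Positive")
SUBTYPES = ("NDC", "Mi2", "TIF1g", "irMyositis")
CONSERVATION_METHODS = ("FFPE", "Cryopreserved")

REQUIRED_SECTIONS = ("Header", "Sample_Attributes", "Lane_Attributes", "Code_Summary")

SHEET_COLUMNS = ["sample_id", "subtype", "cartridge", "fov", "conservation", "patient_id"]


@dataclass(frozen=True)
class ProbeDefinition:
    """One probe of a CodeSet panel."""

    name: str
    code_class: str
    accession: str = ""

    def __post_init__(self) -> None:
        if self.code_class not in CODE_CLASSES:
            raise ValidationError(
                f"probe {self.name!r}: unknown code class {self.code_class!r}; "
                f"expected one of {CODE_CLASSES}"
            )


@dataclass(frozen=True)
class SampleAttributes:
    """Study-level attributes of one profiled sample.

    ``subtype``, ``cartridge``, ``conservation`` and ``patient_id`` come from
    the sample sheet; they are ``None`` on a freshly parsed RCC record.
    """

    sample_id: str
    subtype: str | None = None
    cartridge: str | None = None
    fov_count: int | None = None
    conservation: str | None = None
    patient_id: str | None = None

    def __post_init__(self) -> None:
        if not self.sample_id:
            raise ValidationError("sample_id must be non-empty")
        if self.subtype is not None and self.subtype not in SUBTYPES:
            raise ValidationError(
                f"sample {self.sample_id!r}: unknown subtype {self.subtype!r}; "
                f"expected one of {SUBTYPES}"
            )
        if self.conservation is not None and self.conservation not in CONSERVATION_METHODS:
            raise ValidationError(
                f"sample {self.sample_id!r}: unknown conservation "
                f"{self.conservation!r}; expected one of {CONSERVATION_METHODS}"
            )
        if self.fov_count is not None and self.fov_count <= 0:
            raise ValidationError(f"sample {self.sample_id!r}: fov_count must be positive")


@dataclass(frozen=True)
class SampleRecord:
    """A single sample: its attributes, panel definition and raw counts."""

    attributes: SampleAttributes
    probes: tuple[ProbeDefinition, ...]
    counts: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        names = [p.name for p in self.probes]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValidationError(f"duplicate probe names in panel: {dupes}")
        if set(self.counts) != set(names):
            missing = sorted(set(names) - set(self.counts))
            extra = sorted(set(self.counts) - set(names))
            raise ValidationError(
                f"counts do not match panel probes (missing={missing[:5]}, extra={extra[:5]})"
            )
        for name, c in self.counts.items():
            if not isinstance(c, (int,)) or isinstance(c, bool) or c < 0:
                raise ValidationError(f"count for probe {name!r} must be a non-negative integer")

    def probe_class_tally(self) -> dict[str, int]:
        tally = {c: 0 for c in CODE_CLASSES}
        for p in self.probes:
            tally[p.code_class] += 1
        return tally


@dataclass
class CountMatrix:
    """Probes x samples count container with annotations.

    ``values`` is a probes x samples DataFrame indexed by probe name with
    sample ids as columns.  ``probe_annotations`` carries name / code_class /
    accession, ``sample_annotations`` carries the sample-sheet metadata in
    column order, ``scale`` is one of raw / cpm / normalized / log2cpm.
    """

    values: pd.DataFrame
    probe_annotations: pd.DataFrame
    sample_annotations: pd.DataFrame
    scale: str = "raw"

    def __post_init__(self) -> None:
        if self.scale not in ("raw", "cpm", "normalized", "log2cpm"):
            raise ValidationError(f"unknown scale {self.scale!r}")
        if list(self.values.index) != list(self.probe_annotations["name"]):
            raise ValidationError("values rows and probe annotations disagree")
        if list(self.values.columns) != list(self.sample_annotations["sample_id"]):
            raise ValidationError("values columns and sample annotations disagree")
        if self.scale == "raw":
            v = self.values.to_numpy()
            if (v < 0).any() or not (v == v.astype(int)).all():
                raise ValidationError("raw counts must be non-negative integers")

    # -- convenience accessors -------------------------------------------------

    def class_mask(self, *classes: str) -> pd.Series:
        mask = self.probe_annotations["code_class"].isin(classes)
        return pd.Series(mask.to_numpy(), index=self.values.index)

    def subset_probes(self, names: Sequence[str]) -> "CountMatrix":
        names = list(names)
        ann = self.probe_annotations.set_index("name").loc[names].reset_index()
        return CountMatrix(
            values=self.values.loc[names],
            probe_annotations=ann,
            sample_annotations=self.sample_annotations.copy(),
            scale=self.scale,
        )

    def library_sizes(self) -> pd.Series:
        """Per-sample library size: total Endogenous + Housekeeping counts.

        Control probes are spike-like and excluded by design.
        """
        mask = self.class_mask("Endogenous", "Housekeeping")
        return self.values.loc[mask.to_numpy()].sum(axis=0).astype(float)


# -- RCC parsing ----------------------------------------------------------------


def _split_sections(lines: list[str], path: str) -> dict[str, list[tuple[int, str]]]:
    sections: dict[str, list[tuple[int, str]]] = {}
    current: str | None = None
    for lineno, raw in enumerate(lines, start=1):
        line = raw.rstrip("\r\n")
        if not line.strip():
            continue
        if line.startswith("</") and line.endswith(">"):
            tag = line[2:-1]
            if tag != current:
                raise RCCFormatError(f"{path}: line {lineno}: unexpected closing tag {tag!r}")
            current = None
        elif line.startswith("<") and line.endswith(">"):
            if current is not None:
                raise RCCFormatError(f"{path}: line {lineno}: nested section {line!r}")
            current = line[1:-1]
            sections.setdefault(current, [])
        else:
            if current is None:
                raise RCCFormatError(f"{path}: line {lineno}: content outside any section")
            sections[current].append((lineno, line))
    if current is not None:
        raise RCCFormatError(f"{path}: section {current!r} never closed")
    return sections


def _section_kv(rows: Iterable[tuple[int, str]]) -> dict[str, str]:
    out: dict[str, str] = {}
    for _, line in rows:
        key, _, value = line.partition(",")
        out[key] = value
    return out


def read_rcc(path: str | Path) -> SampleRecord:
    """Parse one RCC file into a :class:`SampleRecord`.

    Raises :class:`RCCFormatError` if a required section is missing or a probe
    name repeats, and :class:`RCCParseError` (with the line number) if a count
    is not an integer.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    sections = _split_sections(lines, str(path))
    for sec in REQUIRED_SECTIONS:
        if sec not in sections:
            raise RCCFormatError(f"{path}: missing {sec}")

    sample_attrs = _section_kv(sections["Sample_Attributes"])
    lane_attrs = _section_kv(sections["Lane_Attributes"])
    sample_id = sample_attrs.get("ID", "") or path.stem
    fov = None
    if "FovCount" in lane_attrs:
        try:
            fov = int(lane_attrs["FovCount"])
        except ValueError as exc:
            raise RCCParseError(f"{path}: FovCount {lane_attrs['FovCount']!r} not an integer") from exc

    code_rows = sections["Code_Summary"]
    if not code_rows:
        raise RCCFormatError(f"{path}: Code_Summary section is empty")
    header_lineno, header = code_rows[0]
    if [c.strip() for c in header.split(",")] != ["CodeClass", "Name", "Accession", "Count"]:
        raise RCCFormatError(
            f"{path}: line {header_lineno}: Code_Summary header must be "
            "'CodeClass,Name,Accession,Count'"
        )
    probes: list[ProbeDefinition] = []
    counts: dict[str, int] = {}
    for lineno, line in code_rows[1:]:
        fields = line.split(",")
        if len(fields) != 4:
            raise RCCFormatError(f"{path}: line {lineno}: expected 4 comma-separated fields")
        code_class, name, accession, count_str = (f.strip() for f in fields)
        if code_class not in CODE_CLASSES:
            raise RCCFormatError(
                f"{path}: line {lineno}: unknown code class {code_class!r} "
                f"(expected one of {CODE_CLASSES})"
            )
        if name in counts:
            raise RCCFormatError(f"{path}: line {lineno}: duplicate probe name {name!r}")
        try:
            count = int(count_str)
        except ValueError as exc:
            raise RCCParseError(
                f"{path}: line {lineno}: count {count_str!r} is not an integer"
            ) from exc
        if count < 0:
            raise RCCParseError(f"{path}: line {lineno}: negative count {count}")
        probes.append(ProbeDefinition(name=name, code_class=code_class, accession=accession))
        counts[name] = count

    return SampleRecord(
        attributes=SampleAttributes(sample_id=sample_id, fov_count=fov),
        probes=tuple(probes),
        counts=counts,
    )


def write_rcc(record: SampleRecord, path: str | Path) -> Path:
    """Serialise a :class:`SampleRecord` to an RCC file (inverse of read_rcc)."""
    path = Path(path)
    attrs = record.attributes
    if not attrs.sample_id:
        raise ValidationError("record is missing required attribute: sample_id")
    lines = [
        "<Header>",
        "FileVersion,1.7",
        "SoftwareVersion,myocounter",
        "</Header>",
        "<Sample_Attributes>",
        f"ID,{attrs.sample_id}",
        "</Sample_Attributes>",
        "<Lane_Attributes>",
        "ID,1",
        f"FovCount,{attrs.fov_count if attrs.fov_count is not None else 555}",
        "</Lane_Attributes>",
        "<Code_Summary>",
        "CodeClass,Name,Accession,Count",
    ]
    for probe in record.probes:
        for piece in (probe.name, probe.accession):
            if "," in piece:
                raise ValidationError(f"probe field {piece!r} contains a comma")
        lines.append(f"{probe.code_class},{probe.name},{probe.accession},{record.counts[probe.name]}")
    lines.append("</Code_Summary>")
    path.write_text("\n".join(lines) + "\n")
    return path


# -- sample sheet ----------------------------------------------------------------


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    """Read the tab-separated sample sheet (sample_id, subtype, cartridge, fov,
    conservation, patient_id), validating enumerations and uniqueness."""
    sheet = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in SHEET_COLUMNS if c not in sheet.columns]
    if missing:
        raise ValidationError(f"sample sheet missing columns: {missing}")
    sheet = sheet[SHEET_COLUMNS].copy()
    sheet["fov"] = sheet["fov"].astype(int)
    if sheet["sample_id"].duplicated().any():
        dupes = sorted(sheet.loc[sheet["sample_id"].duplicated(), "sample_id"])
        raise ValidationError(f"duplicate sample ids in sheet: {dupes}")
    bad = sorted(set(sheet["subtype"]) - set(SUBTYPES))
    if bad:
        raise ValidationError(f"unknown subtypes in sheet: {bad}")
    bad = sorted(set(sheet["conservation"]) - set(CONSERVATION_METHODS))
    if bad:
        raise ValidationError(f"unknown conservation methods in sheet: {bad}")
    return sheet


def write_sample_sheet(sheet: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    sheet[SHEET_COLUMNS].to_csv(path, sep="\t", index=False)
    return path


def assemble_count_matrix(
    records: Sequence[SampleRecord], sheet: pd.DataFrame
) -> CountMatrix:
    """Combine per-sample records with the sample sheet into a raw CountMatrix.

    Columns follow sheet order; all records must share an identical panel and
    every record must appear in the sheet.
    """
    if not records:
        raise ValidationError("no records to assemble")
    ref = records[0]
    ref_names = [p.name for p in ref.probes]
    for rec in records[1:]:
        names = [p.name for p in rec.probes]
        if set(names) != set(ref_names):
            diff = sorted(set(names) ^ set(ref_names))
            raise ValidationError(
                f"probe sets differ between samples {ref.attributes.sample_id!r} and "
                f"{rec.attributes.sample_id!r}; symmetric difference: {diff}"
            )
    by_id = {rec.attributes.sample_id: rec for rec in records}
    if len(by_id) != len(records):
        raise ValidationError("duplicate sample ids among records")
    not_in_sheet = sorted(set(by_id) - set(sheet["sample_id"]))
    if not_in_sheet:
        raise ValidationError(f"samples present in records but not in sheet: {not_in_sheet}")
    sheet = sheet[sheet["sample_id"].isin(by_id)].reset_index(drop=True)

    values = pd.DataFrame(
        {sid: [by_id[sid].counts[name] for name in ref_names] for sid in sheet["sample_id"]},
        index=pd.Index(ref_names, name="probe"),
    )
    probe_ann = pd.DataFrame(
        {
            "name": ref_names,
            "code_class": [p.code_class for p in ref.probes],
            "accession": [p.accession for p in ref.probes],
        }
    )
    sample_ann = sheet.copy()
    for sid in sample_ann["sample_id"]:
        rec_fov = by_id[sid].attributes.fov_count
        if rec_fov is not None:
            sample_ann.loc[sample_ann["sample_id"] == sid, "fov"] = rec_fov
    return CountMatrix(values=values, probe_annotations=probe_ann, sample_annotations=sample_ann, scale="raw")


def records_equal(a: SampleRecord, b: SampleRecord) -> bool:
    """Structural equality modulo attributes that RCC files do not carry."""
    return (
        a.attributes.sample_id == b.attributes.sample_id
        and a.attributes.fov_count == b.attributes.fov_count
        and a.probes == b.probes
        and dict(a.counts) == dict(b.counts)
    )
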