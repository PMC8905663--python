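"""Typed data model and file IO for the pipeline.

Every table the pipeline touches goes through this module: component
property tables (TSV/CSV), component–target and target–target edge lists
(two-column TSV or three-column SIF), GMT gene-set annotations, herb dose
tables and the JSON run manifest.  All readers are deterministic: output
order follows input order with lexicographic tie-breaks, so a re-run on
identical inputs is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "ComponentRecord",
    "HerbDose",
    "EdgeTable",
    "AnnotationTerm",
    "RunManifest",
    "SchemaError",
    "ParseError",
    "read_component_table",
    "read_dose_table",
    "read_edge_table",
    "read_gmt",
    "write_results",
]


class SchemaError(ValueError):
    """A required column or field is missing or malformed."""


class ParseError(ValueError):
    """A row or line failed to parse; message carries the line number."""


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class ComponentRecord:
    """One candidate chemical with its physicochemical properties.

    ``herbs`` holds the source herb label(s); a component present in more
    than one herb (a shared component) carries all of them.  ``mw`` is the
    molecular weight in Da, ``rbn`` the rotatable-bond count, ``n_hacc`` /
    ``n_hdon`` the hydrogen-bond acceptor/donor counts and ``clogp`` the
    consensus logP.  ``concentration`` is mg of component per g of raw
    herb, when a measured value is available.
    """

    component_id: str
    name: str
    herbs: frozenset[str]
    mw: float
    rbn: int
    n_hacc: int
    n_hdon: int
    clogp: float
    concentration: float | None = None
    smiles: str | None = None

    def __post_init__(self) -> None:
        if not self.herbs:
            raise ValueError(f"{self.component_id}: herbs must be non-empty")
        if not (self.mw > 0):
            raise ValueError(f"{self.component_id}: mw must be positive")
        for fname in ("rbn", "n_hacc", "n_hdon"):
            v = getattr(self, fname)
            if not (isinstance(v, int) and v >= 0):
                raise ValueError(f"{self.component_id}: {fname} must be a non-negative integer")
        if not math.isfinite(self.clogp):
            raise ValueError(f"{self.component_id}: clogp must be finite")


@dataclass(frozen=True)
class HerbDose:
    """Mass of raw herb (grams) in one formula dose."""

    herb: str
    grams: float

    def __post_init__(self) -> None:
        if not (self.grams > 0):
            raise ValueError(f"{self.herb}: grams must be positive")


@dataclass(frozen=True)
class EdgeTable:
    """Deduplicated, order-preserving undirected edge list."""

    edges: tuple[tuple[str, str], ...]
    kind: str  # "component-target" | "target-target"

    def __post_init__(self) -> None:
        if self.kind not in ("component-target", "target-target"):
            raise ValueError(f"unknown edge kind {self.kind!r}")


@dataclass(frozen=True)
class AnnotationTerm:
    """One gene set of a GMT annotation."""

    term_id: str
    term_name: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"{self.term_id}: gene set must be non-empty")


@dataclass
class RunManifest:
    """Reproducibility record written next to every result set.

    ``timestamp`` is null unless explicitly recorded, so that re-running
    with identical inputs and seed produces byte-identical output files.
    """

    inputs: dict[str, str] = field(default_factory=dict)  # path -> sha256
    config: dict = field(default_factory=dict)
    seed: int | None = None
    version: str = ""
    timestamp: str | None = None

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunManifest":
        return cls(**json.loads(text))


# ---------------------------------------------------------------------------
# helpers

_WS = re.compile(r"\s+")


def normalize_name(name: str) -> str:
    """Case-insensitive, whitespace-collapsed component name key."""
    return _WS.sub(" ", name.strip()).casefold()


def _slug(name: str) -> str:
    s = re.sub(r"[^0-9a-z]+", "-", normalize_name(name)).strip("-")
    return s or "component"


def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _read_table(path: str | Path) -> pd.DataFrame:
    """Read a delimited text table, auto-detecting TSV vs CSV."""
    with open(path, "r", encoding="utf-8") as fh:
        sample = fh.read(4096)
    sep = "\t" if "\t" in sample.splitlines()[0] else ","
    return pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False, encoding="utf-8")


_PROPERTY_COLUMNS = {
    "name": ("name", "molecule name", "component", "molecule"),
    "source": ("source", "herb", "herbs"),
    "mw": ("mw",),
    "rbn": ("rbn",),
    "n_hacc": ("nhacc", "n_hacc"),
    "n_hdon": ("nhdon", "n_hdon"),
    "clogp": ("clogp",),
    "concentration": ("concentration_mg_per_g", "concentration"),
    "smiles": ("smiles",),
}


def _match_columns(columns: Sequence[str]) -> dict[str, str]:
    lookup = {c.strip().casefold(): c for c in columns}
    found: dict[str, str] = {}
    for canon, aliases in _PROPERTY_COLUMNS.items():
        for a in aliases:
            if a in lookup:
                found[canon] = lookup[a]
                break
    required = ("name", "source", "mw", "rbn", "n_hacc", "n_hdon", "clogp")
    missing = [c for c in required if c not in found]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    return found


# ---------------------------------------------------------------------------
# readers


def read_component_table(
    path: str | Path,
    merge: str = "by-name",
    concentrations: Mapping[str, float] | None = None,
) -> list[ComponentRecord]:
    """Read a component property table.

    The table needs columns name, source, MW, RBN, nHAcc, nHDon, ClogP
    (case-insensitive; TSV or CSV) and may carry optional
    ``concentration_mg_per_g`` and ``smiles`` columns.  A blank source cell
    inherits the nearest source above it, matching how multi-row herb
    blocks are commonly printed.

    merge="by-name" (default) merges rows whose normalized names match
    *across different herbs* into a single multi-herb record — the shared-
    component semantics the merge exists for.  Same-name rows listed twice
    under one herb are distinct upstream entries and are kept as separate
    records with disambiguated ids.  merge="off" keeps every row distinct.

    ``concentrations`` optionally maps component names to mg/g values and
    overrides/extends the table's own concentration column.
    """
    if merge not in ("by-name", "off"):
        raise ValueError(f"unknown merge policy {merge!r}")
    df = _read_table(path)
    cols = _match_columns(df.columns)

    conc_lookup = {normalize_name(k): float(v) for k, v in (concentrations or {}).items()}

    rows: list[dict] = []
    last_source = ""
    for idx, row in df.iterrows():
        line_no = idx + 2  # header is line 1
        name = str(row[cols["name"]]).strip()
        if not name:
            raise ParseError(f"line {line_no}: empty component name")
        source = str(row[cols["source"]]).strip() or last_source
        if not source:
            raise ParseError(f"line {line_no}: no source herb (and none to inherit)")
        last_source = source
        try:
            mw = float(row[cols["mw"]])
            rbn = int(float(row[cols["rbn"]]))
            n_hacc = int(float(row[cols["n_hacc"]]))
            n_hdon = int(float(row[cols["n_hdon"]]))
            clogp = float(row[cols["clogp"]])
        except ValueError as exc:
            raise ParseError(f"line {line_no}: non-numeric property value ({exc})") from None
        conc: float | None = None
        if "concentration" in cols:
            raw = str(row[cols["concentration"]]).strip()
            if raw:
                conc = float(raw)
        if conc is None:
            conc = conc_lookup.get(normalize_name(name))
        smiles = None
        if "smiles" in cols:
            smiles = str(row[cols["smiles"]]).strip() or None
        rows.append(
            dict(name=name, herb=source, mw=mw, rbn=rbn, n_hacc=n_hacc,
                 n_hdon=n_hdon, clogp=clogp, concentration=conc, smiles=smiles)
        )

    return _assemble_records(rows, merge)


def _assemble_records(rows: list[dict], merge: str) -> list[ComponentRecord]:
    # occurrence index of a name within its herb: the k-th occurrence under
    # herb A merges with the k-th occurrence under herb B, never with the
    # (k+1)-th under its own herb.
    seen_in_herb: dict[tuple[str, str], int] = {}
    groups: dict[tuple[str, int], list[dict]] = {}
    order: list[tuple[str, int]] = []
    for i, r in enumerate(rows):
        key_name = normalize_name(r["name"])
        if merge == "off":
            key = (key_name, i)
        else:
            occ = seen_in_herb.get((key_name, r["herb"]), 0)
            seen_in_herb[(key_name, r["herb"])] = occ + 1
            key = (key_name, occ)
        if key not in groups:
            groups[key] = []
            order.append(key)
        groups[key].append(r)

    used_ids: dict[str, int] = {}
    records: list[ComponentRecord] = []
    for key in order:
        grp = groups[key]
        first = grp[0]
        for other in grp[1:]:
            for f in ("mw", "rbn", "n_hacc", "n_hdon", "clogp"):
                if abs(float(other[f]) - float(first[f])) > 1e-6:
                    raise ParseError(
                        f"conflicting {f} for merged component {first['name']!r}: "
                        f"{first[f]} vs {other[f]}"
                    )
        herbs = frozenset(r["herb"] for r in grp)
        conc = next((r["concentration"] for r in grp if r["concentration"] is not None), None)
        smiles = next((r["smiles"] for r in grp if r["smiles"] is not None), None)
        base = _slug(first["name"])
        n = used_ids.get(base, 0)
        used_ids[base] = n + 1
        cid = base if n == 0 else f"{base}-{n + 1}"
        records.append(
            ComponentRecord(
                component_id=cid, name=first["name"], herbs=herbs,
                mw=float(first["mw"]), rbn=int(first["rbn"]),
                n_hacc=int(first["n_hacc"]), n_hdon=int(first["n_hdon"]),
                clogp=float(first["clogp"]), concentration=conc, smiles=smiles,
            )
        )
    return records


def read_dose_table(path: str | Path) -> list[HerbDose]:
    """Read a two-column herb/grams dose table (TSV or CSV)."""
    df = _read_table(path)
    lookup = {c.strip().casefold(): c for c in df.columns}
    if "herb" not in lookup or "grams" not in lookup:
        raise SchemaError("dose table needs columns 'herb' and 'grams'")
    doses = []
    for idx, row in df.iterrows():
        try:
            doses.append(HerbDose(str(row[lookup["herb"]]).strip(), float(row[lookup["grams"]])))
        except ValueError as exc:
            raise ParseError(f"line {idx + 2}: {exc}") from None
    return doses


def read_edge_table(path: str | Path, kind: str) -> EdgeTable:
    """Read a two-column edge list or three-column SIF file.

    SIF lines look like ``a <relation> b``; the relation token is ignored.
    Duplicate pairs are collapsed keeping first-seen order; for the
    component-target kind a self-loop is an error (the graph is bipartite).
    """
    edges: list[tuple[str, str]] = []
    seen: set[tuple[str, str]] = set()
    with open(path, "r", encoding="utf-8") as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) == 2:
                a, b = parts
            elif len(parts) == 3:
                a, _, b = parts
            else:
                raise ParseError(f"line {line_no}: expected 2 (TSV) or 3 (SIF) fields, got {len(parts)}")
            if not a or not b:
                raise ParseError(f"line {line_no}: empty endpoint")
            if a == b and kind == "component-target":
                raise ParseError(f"line {line_no}: self-loop {a!r} not allowed in component-target edges")
            pair = (a, b)
            canon = pair if kind == "component-target" else tuple(sorted(pair))
            if canon in seen:
                continue
            seen.add(canon)
            edges.append(pair)
    return EdgeTable(edges=tuple(edges), kind=kind)


def read_gmt(path: str | Path, uppercase_genes: bool = True) -> list[AnnotationTerm]:
    """Read a Broad-convention GMT file: term, description, then genes."""
    terms: list[AnnotationTerm] = []
    seen_ids: set[str] = set()
    with open(path, "r", encoding="utf-8") as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(f"line {line_no}: GMT needs term, description and >=1 gene")
            term_id, desc, *genes = parts
            genes = [g.strip() for g in genes if g.strip()]
            if not genes:
                raise ParseError(f"line {line_no}: empty gene list for term {term_id!r}")
            if uppercase_genes:
                genes = [g.upper() for g in genes]
            if term_id in seen_ids:
                raise ParseError(f"line {line_no}: duplicate term id {term_id!r}")
            seen_ids.add(term_id)
            terms.append(AnnotationTerm(term_id=term_id, term_name=desc, genes=frozenset(genes)))
    return terms


# ---------------------------------------------------------------------------
# writers


def components_to_frame(records: Iterable[ComponentRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append(
            {
                "component_id": r.component_id,
                "name": r.name,
                "herbs": ";".join(sorted(r.herbs)),
                "MW": r.mw,
                "RBN": r.rbn,
                "nHAcc": r.n_hacc,
                "nHDon": r.n_hdon,
                "ClogP": r.clogp,
                "concentration_mg_per_g": "" if r.concentration is None else r.concentration,
                "smiles": r.smiles or "",
            }
        )
    return pd.DataFrame(rows)


def write_results(
    results: Mapping[str, pd.DataFrame],
    out_dir: str | Path,
    manifest: RunManifest | None = None,
) -> RunManifest:
    """Write each named DataFrame as ``<name>.tsv`` plus ``manifest.json``.

    Output is byte-identical across re-runs with the same inputs and seed:
    tables are written untouched in their given row order and the manifest
    records input checksums rather than wall-clock time.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = manifest or RunManifest()
    for name, frame in results.items():
        dest = out / f"{name}.tsv"
        frame.to_csv(dest, sep="\t", index=False, lineterminator="\n")
        manifest.inputs.setdefault(f"output:{name}.tsv", sha256_file(dest))
    (out / "manifest.json").write_text(manifest.to_json() + "\n", encoding="utf-8")
    return manifest
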