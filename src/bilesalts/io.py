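"""Readers and writers for the pipeline's plain-text formats.

Formats handled:

* species-profile tables — long-format CSV, one row per compound, header
  ``species,family,order_group,diet,compound,percent``; percent values may
  carry a ``~`` prefix (or "approximately"/"ca.") which parses to the bare
  number with an *approximate* flag;
* peak lists — CSV with header ``mz,intensity``;
* annotation reports — CSV with columns
  ``peak_mz,candidate_label,formula,theoretical_mz,delta_mz,conjugation``;
* Newick trees (via dendropy; quoted labels and polytomies supported);
* protein FASTA (via Biopython);
* character matrices — long CSV ``species,character,state``;
* run manifests — JSON records of command, config, input digests, seed and
  version, emitted once per CLI run.

Unparseable compound names are collected into an error report rather than
silently dropped; missing required columns and duplicate species+compound
rows raise :class:`~bilesalts.errors.SchemaError`.  Numeric output precision
is fixed (one decimal for percents, four for m/z) so identical inputs give
byte-identical files.
"""

from __future__ import annotations

import hashlib
import json
import re
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import dendropy
import pandas as pd

from . import __version__
from .compounds import PeakAnnotation, formula_string, molecular_formula, parse_name
from .errors import BileSaltError, ParseError, SchemaError, ValidationError
from .profiles import ProfileComponent, SpeciesProfile

__all__ = [
    "ProfileReadResult",
    "read_profile_table",
    "write_profile_table",
    "read_peak_list",
    "write_peak_list",
    "write_annotation_report",
    "read_newick",
    "write_newick",
    "read_fasta",
    "read_character_matrix",
    "write_crosstab",
    "write_conservation",
    "write_ancestral",
    "RunManifest",
]

_PROFILE_COLUMNS = ["species", "family", "order_group", "diet", "compound", "percent"]

_APPROX_RE = re.compile(r"^\s*(?:~|approx\.?|approximately|ca\.?)\s*", re.IGNORECASE)


def parse_percent(raw) -> tuple[float, bool]:
    """Parse a percent cell; "~100" and "approximately 100" -> (100.0, True)."""
    if isinstance(raw, (int, float)):
        return float(raw), False
    text = str(raw).strip()
    stripped = _APPROX_RE.sub("", text)
    approximate = stripped != text
    try:
        return float(stripped), approximate
    except ValueError:
        raise ValidationError(f"cannot parse percent value {raw!r}") from None


@dataclass
class ProfileReadResult:
    profiles: list
    errors: list  # (row_number, compound, message) for unparseable rows

    def __iter__(self):
        return iter(self.profiles)


def read_profile_table(path) -> ProfileReadResult:
    """Read a long-format species-profile CSV.

    Rows whose compound name cannot be parsed are collected into
    ``result.errors`` (1-based data row numbers) instead of being dropped
    silently.  A missing required column raises :class:`SchemaError`, as
    does a duplicated species+compound pair.
    """
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in _PROFILE_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    dup = frame.duplicated(subset=["species", "compound"], keep=False)
    if dup.any():
        rows = [int(i) + 1 for i in frame.index[dup]]
        raise SchemaError(f"{path}: duplicate species+compound rows {rows}")

    errors: list[tuple[int, str, str]] = []
    grouped: dict[str, dict] = {}
    for i, row in frame.iterrows():
        row_number = int(i) + 1
        try:
            descriptor = parse_name(row["compound"])
            percent, approximate = parse_percent(row["percent"])
            component = ProfileComponent(
                descriptor=descriptor, percent=percent,
                approximate=approximate, name=row["compound"],
            )
        except (ParseError, ValidationError) as exc:
            errors.append((row_number, row["compound"], str(exc)))
            continue
        meta = grouped.setdefault(
            row["species"],
            {"family": row["family"], "order_or_group": row["order_group"],
             "diet": row["diet"] or None, "components": []},
        )
        meta["components"].append(component)

    profiles = [
        SpeciesProfile(
            species=species, family=meta["family"],
            order_or_group=meta["order_or_group"], diet=meta["diet"],
            components=tuple(meta["components"]),
        )
        for species, meta in grouped.items()
    ]
    return ProfileReadResult(profiles=profiles, errors=errors)


def write_profile_table(profiles: Sequence[SpeciesProfile], path) -> None:
    rows = []
    for p in profiles:
        for c in p.components:
            rows.append({
                "species": p.species,
                "family": p.family,
                "order_group": p.order_or_group,
                "diet": p.diet or "",
                "compound": c.name or str(c.descriptor),
                "percent": ("~" if c.approximate else "") + _fmt(c.percent, 4),
            })
    pd.DataFrame(rows, columns=_PROFILE_COLUMNS).to_csv(path, index=False)


def _fmt(x: float, decimals: int) -> str:
    s = f"{x:.{decimals}f}".rstrip("0").rstrip(".")
    return s if s else "0"


# ---------------------------------------------------------------------------
# Peak lists and annotation reports
# ---------------------------------------------------------------------------

def read_peak_list(path) -> list[tuple[float, float]]:
    frame = pd.read_csv(path)
    for col in ("mz", "intensity"):
        if col not in frame.columns:
            raise SchemaError(f"{path}: missing required column {col!r}")
    peaks = [(float(m), float(i)) for m, i in zip(frame["mz"], frame["intensity"])]
    for mz, _ in peaks:
        if mz <= 0:
            raise ValidationError(f"{path}: non-positive m/z {mz}")
    return peaks


def write_peak_list(peaks: Iterable[tuple[float, float]], path) -> None:
    frame = pd.DataFrame(peaks, columns=["mz", "intensity"])
    frame["mz"] = frame["mz"].map(lambda v: f"{v:.4f}")
    frame["intensity"] = frame["intensity"].map(lambda v: f"{v:.4f}")
    frame.to_csv(path, index=False)


def write_annotation_report(annotations: Sequence[Sequence[PeakAnnotation]], path) -> None:
    rows = []
    for hits in annotations:
        for a in hits:
            rows.append({
                "peak_mz": f"{a.peak_mz:.4f}",
                "candidate_label": a.candidate.label,
                "formula": formula_string(
                    molecular_formula(a.candidate.representative())
                ),
                "theoretical_mz": f"{a.theoretical_mz:.4f}",
                "delta_mz": f"{a.delta_mz:.4f}",
                "conjugation": a.candidate.conjugation.value,
            })
    columns = ["peak_mz", "candidate_label", "formula", "theoretical_mz",
               "delta_mz", "conjugation"]
    pd.DataFrame(rows, columns=columns).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Trees, sequences, character matrices
# ---------------------------------------------------------------------------

def read_newick(path) -> dendropy.Tree:
    return dendropy.Tree.get(path=str(path), schema="newick",
                             preserve_underscores=True)


def write_newick(tree: dendropy.Tree, path) -> None:
    tree.write(path=str(path), schema="newick", unquoted_underscores=True)


def read_fasta(path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def read_character_matrix(path):
    from .phylo import CharacterMatrix

    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    for col in ("species", "character", "state"):
        if col not in frame.columns:
            raise SchemaError(f"{path}: missing required column {col!r}")
    characters: dict[str, dict] = {}
    species: list[str] = []
    for _, row in frame.iterrows():
        if row["species"] not in species:
            species.append(row["species"])
        col = characters.setdefault(row["character"], {})
        col[row["species"]] = row["state"] if row["state"] != "" else None
    return CharacterMatrix(species=species, characters=characters)


# ---------------------------------------------------------------------------
# Report writers
# ---------------------------------------------------------------------------

def write_crosstab(report, path, fmt: str = "csv") -> None:
    """Crosstab report as CSV or as an aligned plain-text table."""
    frame = report.to_frame()
    path = Path(path)
    if fmt == "csv":
        with open(path, "w") as fh:
            fh.write(f"# primarily_C27_acids: {report.primarily_definition}\n")
            frame.to_csv(fh, index=False, float_format="%.1f")
    elif fmt == "text":
        with open(path, "w") as fh:
            fh.write(frame.to_string(index=False, float_format=lambda v: f"{v:.1f}"))
            fh.write(f"\n\nprimarily_C27_acids = {report.primarily_definition}\n")
            fh.write(f"n_total = {report.n_total}; unlabeled excluded = "
                     f"{report.n_unlabeled}\n")
    else:
        raise SchemaError(f"unknown report format {fmt!r}")


def write_conservation(groups, path) -> None:
    rows = [
        {
            "group": g.group,
            "n_species": g.n_species,
            "classes": "|".join(sorted(c.value for c in g.classes)),
            "heterogeneous": str(g.heterogeneous).lower(),
            "types_overlap": str(g.types_overlap).lower(),
        }
        for g in groups
    ]
    pd.DataFrame(
        rows, columns=["group", "n_species", "classes", "heterogeneous",
                       "types_overlap"],
    ).to_csv(path, index=False)


def write_ancestral(tree: dendropy.Tree, reconstruction, path) -> None:
    """Per-node state sets, in preorder traversal order."""
    rows = []
    for i, node in enumerate(tree.preorder_node_iter()):
        states = reconstruction.node_states.get(node)
        if states is None:
            continue
        label = node.taxon.label if node.taxon else (node.label or f"node{i}")
        rows.append({
            "node": label,
            "kind": "tip" if node.is_leaf() else "internal",
            "states": "|".join(sorted(map(str, states))),
        })
    with open(path, "w") as fh:
        fh.write(f"# minimal changes: {reconstruction.change_count}\n")
        pd.DataFrame(rows, columns=["node", "kind", "states"]).to_csv(fh, index=False)


# ---------------------------------------------------------------------------
# Run manifests
# ---------------------------------------------------------------------------

def _digest(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    command: str
    config: dict = field(default_factory=dict)
    input_digests: dict = field(default_factory=dict)
    seed: int | None = None
    timestamp: str = ""
    version: str = ""

    @classmethod
    def create(cls, command: str, inputs: Sequence = (), seed: int | None = None,
               **config) -> "RunManifest":
        import datetime

        return cls(
            command=command,
            config=config,
            input_digests={str(p): _digest(p) for p in inputs},
            seed=seed,
            timestamp=datetime.datetime.now(datetime.timezone.utc).isoformat(),
            version=__version__,
        )

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")
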