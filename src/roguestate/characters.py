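"""Morphological character handling: carpel-fusion records and codings.

The analysis character is binary — carpels free (``absent``, 0) versus carpels
united (``present``, 1).  Raw observations distinguish *how* carpels are
united: congenital fusion (united from inception, syncarpy in the narrow
sense), postgenital fusion (initially free surfaces fusing later), both in one
gynoecium, or none.  Monomerous (one-carpel) gynoecia make the character
inapplicable; inapplicable and unknown cells are both treated as missing data
for reconstruction, but kept distinct in the records so reports can tell
"?" from "-".

Two coding schemes turn raw records into the analysis character:

``any_fusion``
    fusion present iff any kind of carpel union was recorded (the original
    scoring of the source matrix);
``congenital_only``
    fusion present iff the union is congenital (postgenitally fused gynoecia
    are re-scored as free-carpellate).

Per-taxon overrides (e.g. scoring *Ceratophyllum* as fused on the
pseudomonomery interpretation, or as unknown) apply after the mode mapping
and win over it.
"""

from __future__ import annotations

import csv
import io
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, FrozenSet, Iterable, List, Mapping, Optional, Tuple, Union

import dendropy

__all__ = [
    "ABSENT",
    "PRESENT",
    "FULL_SET",
    "CharacterError",
    "FusionRecord",
    "CharacterColumn",
    "CodingScheme",
    "read_matrix",
    "write_records_csv",
    "apply_coding",
    "column_summary",
]

ABSENT = 0
PRESENT = 1
FULL_SET: FrozenSet[int] = frozenset({ABSENT, PRESENT})

_ANY_VALUES = {"yes", "no", "unknown", "inapplicable"}
_TYPE_VALUES = {"congenital", "postgenital", "both", "none", "unknown"}

#: Figure-legend shorthand used in compact fixtures: Fr = carpels free,
#: Cf = congenital fusion, Pf = postgenital fusion, C-Pf = both, ? = unknown
#: or monomerous.
_CODE_MAP = {
    "Fr": ("no", "none"),
    "Cf": ("yes", "congenital"),
    "Pf": ("yes", "postgenital"),
    "C-Pf": ("yes", "both"),
    "C/Pf": ("yes", "both"),
    "?": ("unknown", "unknown"),
    "-": ("inapplicable", "unknown"),
}


class CharacterError(ValueError):
    pass


@dataclass(frozen=True)
class FusionRecord:
    """Raw carpel-fusion observation for one taxon."""

    taxon: str
    fusion_present_any: str  # yes | no | unknown | inapplicable
    fusion_type: str = "unknown"  # congenital | postgenital | both | none | unknown

    def __post_init__(self):
        if self.fusion_present_any not in _ANY_VALUES:
            raise CharacterError(
                f"{self.taxon}: bad fusion_present_any {self.fusion_present_any!r}")
        if self.fusion_type not in _TYPE_VALUES:
            raise CharacterError(
                f"{self.taxon}: bad fusion_type {self.fusion_type!r}")
        if self.fusion_present_any == "no" and self.fusion_type != "none":
            raise CharacterError(
                f"{self.taxon}: fusion absent but fusion_type={self.fusion_type!r}")
        if self.fusion_type == "none" and self.fusion_present_any == "yes":
            raise CharacterError(
                f"{self.taxon}: fusion present but fusion_type='none'")
        if (self.fusion_type in ("congenital", "postgenital", "both")
                and self.fusion_present_any != "yes"):
            raise CharacterError(
                f"{self.taxon}: fusion_type={self.fusion_type!r} implies "
                "fusion is present")

    @classmethod
    def from_code(cls, taxon: str, code: str) -> "FusionRecord":
        """Build a record from figure-legend shorthand (Fr/Cf/Pf/C-Pf/?/-)."""
        try:
            any_, type_ = _CODE_MAP[code.strip()]
        except KeyError:
            raise CharacterError(f"{taxon}: unknown fusion code {code!r}") from None
        return cls(taxon, any_, type_)


@dataclass(frozen=True)
class CharacterColumn:
    """Per-taxon state sets for one binary character.

    Every taxon carries a non-empty subset of ``{absent, present}``; missing
    and inapplicable taxa carry the full set.
    """

    states: Mapping[str, FrozenSet[int]]

    def __post_init__(self):
        for taxon, ss in self.states.items():
            if not ss or not frozenset(ss) <= FULL_SET:
                raise CharacterError(f"{taxon}: invalid state set {ss!r}")

    def __getitem__(self, taxon: str) -> FrozenSet[int]:
        return self.states[taxon]

    def __contains__(self, taxon: str) -> bool:
        return taxon in self.states

    @property
    def taxa(self) -> List[str]:
        return list(self.states)

    def present_taxa(self) -> FrozenSet[str]:
        return frozenset(t for t, s in self.states.items()
                         if s == frozenset({PRESENT}))


@dataclass(frozen=True)
class CodingScheme:
    """Rule mapping raw fusion records to the analysis character.

    ``metadata`` is documentation only (e.g. the convention that carpels count
    as fused when united for more than 5% of their length, which requires
    specimen measurements and is never computed here); it must not and does
    not alter any computation.
    """

    mode: str  # any_fusion | congenital_only
    overrides: Mapping[str, FrozenSet[int]] = field(default_factory=dict)
    metadata: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self):
        if self.mode not in {"any_fusion", "congenital_only"}:
            raise CharacterError(f"bad coding mode {self.mode!r}")
        for taxon, ss in self.overrides.items():
            if not ss or not frozenset(ss) <= FULL_SET:
                raise CharacterError(f"override for {taxon}: bad state set {ss!r}")

    def to_json(self) -> str:
        return json.dumps({
            "mode": self.mode,
            "overrides": {t: sorted(ss) for t, ss in self.overrides.items()},
            "metadata": dict(self.metadata),
        }, sort_keys=True)


def _map_record(record: FusionRecord, mode: str) -> FrozenSet[int]:
    if mode == "any_fusion":
        if record.fusion_present_any == "yes":
            return frozenset({PRESENT})
        if record.fusion_present_any == "no":
            return frozenset({ABSENT})
        return FULL_SET
    # congenital_only
    if record.fusion_type in ("congenital", "both"):
        return frozenset({PRESENT})
    if record.fusion_type in ("postgenital", "none"):
        return frozenset({ABSENT})
    return FULL_SET


def apply_coding(records: Iterable[FusionRecord],
                 scheme: CodingScheme) -> CharacterColumn:
    """Map raw records to a binary character column under a coding scheme.

    Deterministic and total: every record yields a non-empty state set.
    Overrides naming taxa absent from the records are an error.
    """
    records = list(records)
    by_taxon = {}
    for rec in records:
        if rec.taxon in by_taxon:
            raise CharacterError(f"duplicate record for taxon {rec.taxon!r}")
        by_taxon[rec.taxon] = rec
    unknown = set(scheme.overrides) - set(by_taxon)
    if unknown:
        raise CharacterError(f"overrides name unknown taxa: {sorted(unknown)}")
    states = {t: _map_record(r, scheme.mode) for t, r in by_taxon.items()}
    for taxon, ss in scheme.overrides.items():
        states[taxon] = frozenset(ss)
    return CharacterColumn(states)


def column_summary(col: CharacterColumn) -> Tuple[int, int, int]:
    """Counts of (absent-only, present-only, ambiguous/missing) taxa."""
    a = sum(1 for s in col.states.values() if s == frozenset({ABSENT}))
    p = sum(1 for s in col.states.values() if s == frozenset({PRESENT}))
    u = sum(1 for s in col.states.values() if s == FULL_SET)
    return a, p, u


# ---------------------------------------------------------------------- I/O

def read_matrix(source: Union[str, Path],
                symbol_map: Optional[Mapping[str, Tuple[str, str]]] = None
                ) -> List[FusionRecord]:
    """Read fusion records from a NEXUS or CSV matrix (format sniffed).

    NEXUS: a ``CHARACTERS``/``DATA`` block whose first character is the binary
    any-fusion character (``0``/``1``), optionally followed by a fusion-type
    character (default symbols ``0``=none, ``1``=congenital, ``2``=postgenital,
    ``3``=both; override via ``symbol_map`` keyed by the type symbol).
    ``?`` is unknown, ``-`` inapplicable, ``{0 1}``-style polymorphism maps to
    unknown (same downstream semantics: either state at zero cost).

    CSV: columns ``taxon,fusion_any,fusion_type`` (extra columns ignored), or
    ``taxon,code`` with figure-legend shorthand.
    """
    text = str(source)
    if "\n" not in text:
        try:
            path = Path(text)
            if path.exists():
                text = path.read_text()
        except OSError:
            pass
    if text.lstrip().upper().startswith("#NEXUS"):
        return _read_nexus(text, symbol_map)
    return _read_csv(text)


_DEFAULT_TYPE_SYMBOLS = {"0": "none", "1": "congenital",
                         "2": "postgenital", "3": "both"}


def _cell_kind(state) -> str:
    """Classify a dendropy state cell: '0'/'1'/symbol, 'unknown', 'gap', 'poly'."""
    sym = state.symbol
    if sym == "?":
        return "unknown"
    if sym == "-":
        return "gap"
    if sym is None or (state.member_states and len(list(state.member_states)) > 1
                       and sym not in ("?",)):
        return "poly"
    return sym


def _read_nexus(text, symbol_map) -> List[FusionRecord]:
    type_symbols = dict(_DEFAULT_TYPE_SYMBOLS)
    if symbol_map:
        type_symbols.update({k: v[1] if isinstance(v, tuple) else v
                             for k, v in symbol_map.items()})
    try:
        matrix = dendropy.StandardCharacterMatrix.get(data=text, schema="nexus")
    except Exception as exc:
        raise CharacterError(f"cannot parse NEXUS matrix: {exc}") from exc
    records = []
    for taxon in matrix:
        row = matrix[taxon]
        if len(row) < 1:
            raise CharacterError(f"{taxon.label}: empty row")
        kind = _cell_kind(row[0])
        if kind == "0":
            any_, type_ = "no", "none"
        elif kind == "1":
            any_, type_ = "yes", "unknown"
        elif kind == "gap":
            any_, type_ = "inapplicable", "unknown"
        elif kind in ("unknown", "poly"):
            any_, type_ = "unknown", "unknown"
        else:
            raise CharacterError(
                f"{taxon.label}, character 1: undeclared symbol {kind!r}")
        if len(row) >= 2 and any_ == "yes":
            tkind = _cell_kind(row[1])
            if tkind in ("unknown", "gap", "poly"):
                type_ = "unknown"
            elif tkind in type_symbols:
                type_ = type_symbols[tkind]
                if type_ == "none":
                    raise CharacterError(
                        f"{taxon.label}: fusion present but type symbol means 'none'")
            else:
                raise CharacterError(
                    f"{taxon.label}, character 2: undeclared symbol {tkind!r}")
        records.append(FusionRecord(taxon.label, any_, type_))
    return records


def _read_csv(text) -> List[FusionRecord]:
    reader = csv.DictReader(io.StringIO(text))
    if reader.fieldnames is None:
        raise CharacterError("empty CSV input")
    fields = [f.strip() for f in reader.fieldnames]
    records = []
    if "code" in fields:
        for i, row in enumerate(reader, start=2):
            records.append(FusionRecord.from_code(row["taxon"].strip(),
                                                  row["code"]))
    elif "fusion_any" in fields and "fusion_type" in fields:
        for i, row in enumerate(reader, start=2):
            try:
                records.append(FusionRecord(row["taxon"].strip(),
                                            row["fusion_any"].strip(),
                                            row["fusion_type"].strip()))
            except CharacterError as exc:
                raise CharacterError(f"CSV line {i}: {exc}") from exc
    else:
        raise CharacterError(
            "CSV must have columns taxon,fusion_any,fusion_type or taxon,code")
    if not records:
        raise CharacterError("no records in matrix")
    return records


def write_records_csv(records: Iterable[FusionRecord],
                      path: Union[str, Path, None] = None) -> str:
    """Serialise records to the canonical CSV dialect (round-trips exactly)."""
    buf = io.StringIO()
    writer = csv.writer(buf)
    writer.writerow(["taxon", "fusion_any", "fusion_type"])
    for rec in records:
        writer.writerow([rec.taxon, rec.fusion_present_any, rec.fusion_type])
    text = buf.getvalue()
    if path is not None:
        Path(path).write_text(text)
    return text
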