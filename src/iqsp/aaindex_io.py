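"""Reading and writing AAindex-1 amino-acid property scales.

The AAindex database collects published scales that assign one real number to
each of the twenty standard amino acids (hydrophobicity indices, secondary
structure propensities, compositional measures, ...).  Each flat-file record
carries an accession (``H`` line), a free-text description (``D`` line) and a
two-row table of twenty values introduced by an ``I`` line whose header fixes
the residue order::

    I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
       0.61    0.60    0.06    0.46    1.07    0.00    0.47    0.07    0.61    2.22
       1.53    1.15    1.18    2.02    1.95    0.05    0.05    2.65    1.88    1.32

Records that contain ``NA`` placeholders cannot be used as peptide features
and are dropped at parse time; the collection records how many were retained
and how many were dropped.
"""

from __future__ import annotations

import difflib
import io
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Iterator, Mapping, TextIO

__all__ = [
    "STANDARD_AMINO_ACIDS",
    "AAINDEX_ROW_ORDER",
    "PropertyTable",
    "PropertyCollection",
    "AAIndexParseError",
    "PropertyLookupError",
    "parse_aaindex",
    "parse_aaindex_file",
    "serialize_aaindex",
    "get_property",
    "load_bundled_scales",
    "collection_to_tsv",
]

#: The twenty standard residues, alphabetical by one-letter code.  This is the
#: canonical ordering used for composition vectors throughout the package.
STANDARD_AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Residue order of the two value rows in an AAindex-1 record (first row then
#: second row).  This is fixed by the format's ``A/L R/K ...`` header, *not*
#: alphabetical; mapping positions explicitly guards every downstream feature
#: against silent misordering.
AAINDEX_ROW_ORDER = "ARNDCQEGHILKMFPSTWYV"


class AAIndexParseError(ValueError):
    """A record violates the AAindex-1 layout (bad value count, missing H line)."""


class PropertyLookupError(KeyError):
    """An accession is absent from a collection; carries nearest matches."""

    def __init__(self, accession: str, candidates: Iterable[str]):
        near = difflib.get_close_matches(accession, list(candidates), n=3, cutoff=0.0)
        msg = f"unknown accession {accession!r}"
        if near:
            msg += f"; nearest matches: {', '.join(near)}"
        super().__init__(msg)
        self.accession = accession
        self.nearest = near


@dataclass(frozen=True)
class PropertyTable:
    """One amino-acid property scale.

    Parameters
    ----------
    accession:
        AAindex identifier, e.g. ``"GRAR740101"``.
    description:
        Free-text description from the record's ``D`` line.
    values:
        Mapping from one-letter residue code to the scale value; exactly the
        twenty standard residues, all finite.
    """

    accession: str
    description: str
    values: Mapping[str, float]

    def __post_init__(self) -> None:
        if not self.accession:
            raise ValueError("accession must be non-empty")
        keys = set(self.values)
        if keys != set(STANDARD_AMINO_ACIDS):
            missing = sorted(set(STANDARD_AMINO_ACIDS) - keys)
            extra = sorted(keys - set(STANDARD_AMINO_ACIDS))
            raise ValueError(
                f"{self.accession}: values must cover exactly the 20 standard "
                f"residues (missing={missing}, unexpected={extra})"
            )
        for res, val in self.values.items():
            v = float(val)
            if v != v or v in (float("inf"), float("-inf")):
                raise ValueError(f"{self.accession}: non-finite value for {res}")

    def value_array(self, order: str = STANDARD_AMINO_ACIDS):
        """Values as a list following *order* (default: alphabetical residues)."""
        return [float(self.values[r]) for r in order]


@dataclass
class PropertyCollection:
    """An ordered set of property tables plus parse bookkeeping.

    ``n_dropped`` counts records discarded because they contained ``NA``
    values; ``len(collection)`` is the number retained.
    """

    tables: dict[str, PropertyTable] = field(default_factory=dict)
    n_dropped: int = 0
    dropped_accessions: list[str] = field(default_factory=list)

    def add(self, table: PropertyTable) -> None:
        if table.accession in self.tables:
            raise ValueError(f"duplicate accession {table.accession!r}")
        self.tables[table.accession] = table

    def __len__(self) -> int:
        return len(self.tables)

    def __iter__(self) -> Iterator[PropertyTable]:
        return iter(self.tables.values())

    def __contains__(self, accession: str) -> bool:
        return accession in self.tables

    @property
    def accessions(self) -> list[str]:
        return list(self.tables)

    def get(self, accession: str) -> PropertyTable:
        try:
            return self.tables[accession]
        except KeyError:
            raise PropertyLookupError(accession, self.tables) from None

    def subset(self, accessions: Iterable[str]) -> "PropertyCollection":
        """New collection restricted to *accessions*, in the given order."""
        sub = PropertyCollection()
        for acc in accessions:
            sub.add(self.get(acc))
        return sub


def _finish_record(
    lines_by_tag: dict[str, list[str]],
    value_tokens: list[str],
    collection: PropertyCollection,
) -> None:
    if "H" not in lines_by_tag:
        raise AAIndexParseError("record without an H (accession) line")
    accession = lines_by_tag["H"][0].split()[0]
    description = " ".join(" ".join(lines_by_tag.get("D", [])).split())
    if len(value_tokens) != 20:
        raise AAIndexParseError(
            f"{accession}: expected 20 values, found {len(value_tokens)}"
        )
    if any(tok.upper() in ("NA", "NA.", "-") for tok in value_tokens):
        collection.n_dropped += 1
        collection.dropped_accessions.append(accession)
        return
    try:
        values = [float(tok) for tok in value_tokens]
    except ValueError as exc:
        raise AAIndexParseError(f"{accession}: unparseable value ({exc})") from None
    table = PropertyTable(
        accession=accession,
        description=description,
        values=dict(zip(AAINDEX_ROW_ORDER, values)),
    )
    collection.add(table)


def parse_aaindex(stream: TextIO | str) -> PropertyCollection:
    """Parse AAindex-1 records from *stream* (file object or string).

    Records containing ``NA`` values are dropped (counted in
    ``collection.n_dropped``); malformed records raise
    :class:`AAIndexParseError` naming the offending accession.
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    collection = PropertyCollection()
    lines_by_tag: dict[str, list[str]] = {}
    value_tokens: list[str] = []
    tag = ""
    in_record = False
    for raw in stream:
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        if line.startswith("//"):
            if in_record:
                _finish_record(lines_by_tag, value_tokens, collection)
            lines_by_tag, value_tokens, tag, in_record = {}, [], "", False
            continue
        if line[0].isalpha() and (len(line) == 1 or line[1] == " "):
            tag = line[0]
            body = line[2:].strip()
            in_record = True
        else:  # continuation line of the current tag
            body = line.strip()
        if not in_record:
            raise AAIndexParseError(f"content outside any record: {line!r}")
        if tag == "I":
            if body and not body.startswith("A/L"):
                value_tokens.extend(body.split())
        else:
            lines_by_tag.setdefault(tag, []).append(body)
    if in_record:
        _finish_record(lines_by_tag, value_tokens, collection)
    return collection


def parse_aaindex_file(path) -> PropertyCollection:
    """Parse an AAindex-1 flat file from *path*."""
    with open(path, "r", encoding="utf-8") as fh:
        return parse_aaindex(fh)


def serialize_aaindex(tables: Iterable[PropertyTable]) -> str:
    """Render tables back to AAindex-1 layout (round-trips through the parser)."""
    chunks = []
    header = ("I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T"
              "     G/W     H/Y     I/V")
    for t in tables:
        row = t.value_array(AAINDEX_ROW_ORDER)
        r1 = "".join(f"{v:8.3f}" for v in row[:10])
        r2 = "".join(f"{v:8.3f}" for v in row[10:])
        chunks.append(
            f"H {t.accession}\nD {t.description}\n{header}\n{r1}\n{r2}\n//\n"
        )
    return "".join(chunks)


def get_property(collection: PropertyCollection, accession: str) -> PropertyTable:
    """Case-sensitive accession lookup; unknown IDs raise with near matches."""
    return collection.get(accession)


def load_bundled_scales() -> PropertyCollection:
    """Load the bundled 18-scale fixture.

    The fixture lists the eighteen informative accessions selected for
    quorum-sensing-peptide prediction with their published descriptions, but
    the per-residue numbers are a deterministic *synthetic* stand-in (the
    licensed database values are not redistributed here).  Suitable for tests
    and demonstrations; for real predictions supply an AAindex-1 file.
    """
    ref = resources.files("iqsp.data").joinpath("aaindex18_synthetic.txt")
    return parse_aaindex(ref.read_text(encoding="utf-8"))


def collection_to_tsv(collection: PropertyCollection) -> str:
    """Tabular export: accession, description, then values A..Y (alphabetical)."""
    out = ["accession\tdescription\t" + "\t".join(STANDARD_AMINO_ACIDS)]
    for t in collection:
        vals = "\t".join(f"{v:g}" for v in t.value_array())
        out.append(f"{t.accession}\t{t.description}\t{vals}")
    return "\n".join(out) + "\n"
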