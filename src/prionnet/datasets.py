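"""Protein records, curated/composite protein sets and disorder tracks.

This module is the I/O layer of the pipeline: FASTA proteomes, the
packaged curated prion sets (KP / EPD / EPN), per-protein intrinsic
disorder annotations, and the composite sets built from the N/Q-rich
prion-like (NQP) list, the protein-binding-domain (PBD) catalog and the
disorder tracks.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

_ISOFORM_RE = re.compile(r"-\d+$")

#: canonical threshold above which a protein counts as "highly disordered"
HIGH_DISORDER_FRACTION = 0.5


def strip_isoform(accession: str) -> str:
    """Map an isoform accession (``P12345-2``) to its canonical form."""
    return _ISOFORM_RE.sub("", accession)


@dataclass(frozen=True)
class ProteinRecord:
    """One proteome entry: a UniProt-style accession and its sequence."""

    accession: str
    sequence: str

    def __post_init__(self):
        if not self.accession:
            raise ValueError("empty accession")

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class ProteinSet:
    """A named set of protein accessions (KP, EPD, EPN, NQP or composite)."""

    name: str
    members: set[str] = field(default_factory=set)

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, accession: str) -> bool:
        return accession in self.members

    def __iter__(self):
        return iter(sorted(self.members))


@dataclass
class DisorderTrack:
    """Per-protein intrinsic-disorder annotation.

    Accepts either a per-residue binary flag string (``flags``) or a
    summary (length, disordered residue count).  When flags are present
    they are authoritative for the counts.
    """

    accession: str
    length: int
    disordered_count: float
    flags: str | None = None

    def __post_init__(self):
        if self.flags is not None:
            if len(self.flags) != self.length:
                raise ValueError(
                    f"{self.accession}: flag string length {len(self.flags)} "
                    f"!= protein length {self.length}"
                )
            self.disordered_count = float(self.flags.count("1"))
        if not 0 <= self.disordered_count <= self.length:
            raise ValueError(f"{self.accession}: disordered count out of range")

    @property
    def fraction(self) -> float:
        return self.disordered_count / self.length if self.length else 0.0


DisorderTracks = dict[str, DisorderTrack]


def _accession_from_header(header: str, lineno: int | None = None) -> str:
    """First-token accession, accepting ``sp|ACC|NAME`` and bare dialects."""
    token = header.split()[0] if header.split() else ""
    if not token:
        where = f" at line {lineno}" if lineno else ""
        raise ValueError(f"malformed FASTA header{where}: {header!r}")
    if "|" in token:
        parts = token.split("|")
        if len(parts) >= 3 and parts[0] in ("sp", "tr"):
            token = parts[1]
        else:
            token = parts[0]
    return strip_isoform(token)


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a proteome FASTA into validated :class:`ProteinRecord` objects.

    Accessions are parsed from the first header token; UniProt
    ``sp|ACC|NAME`` / ``tr|ACC|NAME`` dialects and bare accessions are
    both accepted.  Duplicate accessions raise ``ValueError``.
    """
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        acc = _accession_from_header(entry.description or entry.id)
        if acc in seen:
            raise ValueError(f"duplicate accession in FASTA: {acc}")
        seen.add(acc)
        records.append(ProteinRecord(acc, str(entry.seq).upper().rstrip("*")))
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    seq_records = [
        SeqRecord(Seq(r.sequence), id=r.accession, description="") for r in records
    ]
    SeqIO.write(seq_records, str(path), "fasta")


def proteome_index(records: Iterable[ProteinRecord]) -> dict[str, ProteinRecord]:
    return {r.accession: r for r in records}


# ---------------------------------------------------------------------------
# curated sets


def load_curated_sets(drop_marginal_kps: bool = False) -> dict[str, ProteinSet]:
    """Load the packaged KP / EPD / EPN membership lists.

    EPD is KP plus the experimentally prionogenic additions, so KP ⊆ EPD
    always holds.  ``drop_marginal_kps`` removes MOD5 (P07884, the one
    non-N/Q-rich known prion) and NEW1 (Q08972, prion-propagating only as
    a subsequence construct) from KP and EPD; both are kept by default.
    """
    by_set: dict[str, set[str]] = {"KP": set(), "EPD_EXTRA": set(), "EPN": set()}
    data = resources.files("prionnet.data").joinpath("curated_sets.tsv").read_text()
    for line in data.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        set_name, accession, _gene = line.split("\t")
        by_set[set_name].add(accession)
    kp = by_set["KP"]
    if drop_marginal_kps:
        kp = kp - {"P07884", "Q08972"}
    return {
        "KP": ProteinSet("KP", set(kp)),
        "EPD": ProteinSet("EPD", kp | by_set["EPD_EXTRA"]),
        "EPN": ProteinSet("EPN", set(by_set["EPN"])),
    }


def read_accession_list(path: str | Path, name: str | None = None) -> ProteinSet:
    """One accession per line; ``#`` starts a comment; isoforms stripped."""
    members: set[str] = set()
    for line in Path(path).read_text().splitlines():
        line = line.split("#")[0].strip()
        if line:
            members.add(strip_isoform(line.split()[0]))
    return ProteinSet(name or Path(path).stem, members)


# ---------------------------------------------------------------------------
# disorder tracks


def read_disorder(path: str | Path) -> DisorderTracks:
    """Read the tab-separated disorder annotation file.

    Two dialects are accepted per line:
    ``accession<TAB>length<TAB>disordered_count`` or
    ``accession<TAB>binary-flag-string`` (one 0/1 character per residue).
    """
    tracks: DisorderTracks = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        acc = strip_isoform(fields[0])
        if len(fields) == 2:
            flags = fields[1]
            if set(flags) - {"0", "1"}:
                raise ValueError(f"line {lineno}: flag string is not binary")
            tracks[acc] = DisorderTrack(acc, len(flags), 0.0, flags=flags)
        elif len(fields) >= 3:
            tracks[acc] = DisorderTrack(acc, int(fields[1]), float(fields[2]))
        else:
            raise ValueError(f"line {lineno}: expected 2 or 3 tab-separated fields")
    return tracks


def write_disorder(tracks: DisorderTracks, path: str | Path) -> None:
    with open(path, "w") as fh:
        for acc in sorted(tracks):
            t = tracks[acc]
            if t.flags is not None:
                fh.write(f"{acc}\t{t.flags}\n")
            else:
                fh.write(f"{acc}\t{t.length}\t{t.disordered_count:g}\n")


def disorder_content(
    pset: ProteinSet, tracks: Mapping[str, DisorderTrack]
) -> tuple[float, int, float]:
    """Total disordered residues, total residues and overall fraction of a set."""
    missing = sorted(a for a in pset.members if a not in tracks)
    if missing:
        raise KeyError(f"missing disorder tracks for: {', '.join(missing)}")
    disordered = sum(tracks[a].disordered_count for a in pset.members)
    total = sum(tracks[a].length for a in pset.members)
    return disordered, total, (disordered / total if total else 0.0)


# ---------------------------------------------------------------------------
# composite sets


def derive_composite_sets(
    nqp: ProteinSet,
    pbd: ProteinSet,
    tracks: Mapping[str, DisorderTrack] | None = None,
    disorder_threshold: float = HIGH_DISORDER_FRACTION,
) -> dict[str, ProteinSet]:
    """Build the composite sets used by the Table-2-style analyses.

    Returns ``PBD_not_NQP``, ``NQP_not_PBD``, ``NQP_and_PBD`` and
    ``disordered_not_NQP`` (proteins with disorder fraction strictly
    greater than ``disorder_threshold`` that are not NQPs).  Proteins
    without a disorder track are excluded from the disorder-derived set
    with a logged warning.
    """
    tracks = tracks or {}
    disordered = {
        acc for acc, t in tracks.items() if t.fraction > disorder_threshold
    }
    if tracks:
        logger.debug("%d proteins above disorder threshold", len(disordered))
    return {
        "PBD_not_NQP": ProteinSet("PBD_not_NQP", pbd.members - nqp.members),
        "NQP_not_PBD": ProteinSet("NQP_not_PBD", nqp.members - pbd.members),
        "NQP_and_PBD": ProteinSet("NQP_and_PBD", nqp.members & pbd.members),
        "disordered_not_NQP": ProteinSet(
            "disordered_not_NQP", disordered - nqp.members
        ),
    }
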