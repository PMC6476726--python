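"""Readers and writers for the external formats the pipeline touches.

Sequence files are plain or gzipped FASTA.  Orthogroup files follow the
OrthoMCL ``groups.txt`` convention (``GROUP: species|gene species|gene ...``).
Assembly composition is emitted as AGP v2.1.  Gene positions travel as a
7-column TSV, Ct measurements as a 4-column CSV and k-mer histograms as a
2-column TSV.

Coordinates are 0-based half-open everywhere inside the package and 1-based
inclusive at the AGP / gene-map boundary, matching the conventions of those
formats.
"""

from __future__ import annotations

import gzip
import io
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence, Union

import dendropy
import pandas as pd

from .errors import DataError, FormatError, InternalError

__all__ = [
    "SeqRecord",
    "OrthoGroup",
    "read_fasta",
    "write_fasta",
    "revcomp",
    "parse_groups",
    "write_groups",
    "write_agp",
    "read_agp",
    "agp_to_fasta",
    "parse_newick",
    "write_newick",
    "read_gene_map",
    "write_gene_map",
    "read_ct_table",
    "write_ct_table",
    "read_khist",
    "write_khist",
]

# ---------------------------------------------------------------------------
# sequences

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# Canonical alphabet is {A,C,G,T,N}.  'U' is treated as 'T'; the remaining
# IUPAC ambiguity codes collapse to 'N' (with a warning) so that downstream
# exact-match logic only ever sees five symbols.
_IUPAC_AMBIGUOUS = set("RYSWKMBDHV")
_NORMALIZE = {c: c for c in "ACGTN"}
_NORMALIZE.update({c.lower(): c for c in "ACGTN"})
_NORMALIZE.update({"U": "T", "u": "T"})
_NORMALIZE.update({c: "N" for c in _IUPAC_AMBIGUOUS})
_NORMALIZE.update({c.lower(): "N" for c in _IUPAC_AMBIGUOUS})


@dataclass(frozen=True)
class SeqRecord:
    """A named nucleotide sequence over the alphabet {A,C,G,T,N}."""

    id: str
    sequence: str
    description: str = ""

    def __len__(self) -> int:
        return len(self.sequence)


def revcomp(seq: str) -> str:
    """Reverse complement over {A,C,G,T,N} (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


def _open_text(path: Union[str, Path], mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fasta(path: Union[str, Path]) -> list[SeqRecord]:
    """Read a (possibly gzipped) FASTA file strictly.

    Sequences are upper-cased, ``U`` becomes ``T`` and IUPAC ambiguity codes
    become ``N`` (with a warning).  Any other character, a duplicate record
    id, an empty file or an empty sequence raises :class:`FormatError`
    naming the offending line.
    """
    records: list[SeqRecord] = []
    seen: set[str] = set()
    header: str | None = None
    header_line = 0
    chunks: list[str] = []
    warned_ambiguous = False

    def flush(line_no: int) -> None:
        nonlocal header, chunks
        if header is None:
            return
        seq = "".join(chunks)
        if not seq:
            raise FormatError(
                f"{path}: record '{header}' (line {header_line}) has an empty sequence"
            )
        fields = header.split(None, 1)
        rid = fields[0]
        desc = fields[1] if len(fields) > 1 else ""
        if rid in seen:
            raise FormatError(
                f"{path}: duplicate sequence id '{rid}' at line {header_line}"
            )
        seen.add(rid)
        records.append(SeqRecord(id=rid, sequence=seq, description=desc))
        header, chunks = None, []

    with _open_text(path) as fh:
        line_no = 0
        for line_no, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line:
                continue
            if line.startswith(">"):
                flush(line_no)
                header = line[1:].strip()
                header_line = line_no
                if not header:
                    raise FormatError(f"{path}: empty FASTA header at line {line_no}")
            else:
                if header is None:
                    raise FormatError(
                        f"{path}: sequence data before first header at line {line_no}"
                    )
                out = []
                for ch in line:
                    norm = _NORMALIZE.get(ch)
                    if norm is None:
                        raise FormatError(
                            f"{path}: illegal character {ch!r} at line {line_no}"
                        )
                    if norm == "N" and ch.upper() in _IUPAC_AMBIGUOUS and not warned_ambiguous:
                        warnings.warn(
                            f"{path}: IUPAC ambiguity codes found (line {line_no}); "
                            "converted to N",
                            stacklevel=2,
                        )
                        warned_ambiguous = True
                    out.append(norm)
                chunks.append("".join(out))
        flush(line_no + 1)
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Iterable[SeqRecord], path: Union[str, Path], width: int = 80) -> None:
    """Write FASTA with fixed-width line wrapping (default 80 columns)."""
    with _open_text(path, "wt") as fh:
        for rec in records:
            head = rec.id if not rec.description else f"{rec.id} {rec.description}"
            fh.write(f">{head}\n")
            seq = rec.sequence
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# orthogroups


@dataclass(frozen=True)
class OrthoGroup:
    """One orthologous group: a mapping species -> member gene ids."""

    group_id: str
    members: Mapping[str, tuple[str, ...]]

    def size(self) -> int:
        return sum(len(v) for v in self.members.values())

    def species(self) -> frozenset[str]:
        return frozenset(self.members)


def parse_groups(source: Union[str, Path, io.TextIOBase]) -> list[OrthoGroup]:
    """Parse an OrthoMCL-style groups file.

    Each line reads ``GROUP_ID: species|gene species|gene ...``.  Species
    tokens are whatever precedes the first ``|`` of each member.  Duplicated
    ``(species, gene)`` pairs inside one group are rejected.
    """
    if isinstance(source, (str, Path)):
        fh = _open_text(source)
        close = True
        name = str(source)
    else:
        fh, close, name = source, False, "<stream>"
    groups: list[OrthoGroup] = []
    try:
        for line_no, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if ":" not in line:
                raise FormatError(f"{name}: line {line_no}: missing ':' separator")
            gid, _, rest = line.partition(":")
            gid = gid.strip()
            if not gid:
                raise FormatError(f"{name}: line {line_no}: empty group id")
            members: dict[str, list[str]] = {}
            seen: set[tuple[str, str]] = set()
            tokens = rest.split()
            if not tokens:
                raise FormatError(f"{name}: line {line_no}: group '{gid}' has no members")
            for tok in tokens:
                if "|" not in tok:
                    raise FormatError(
                        f"{name}: line {line_no}: member '{tok}' lacks a 'species|gene' separator"
                    )
                sp, _, gene = tok.partition("|")
                if not sp or not gene:
                    raise FormatError(
                        f"{name}: line {line_no}: malformed member '{tok}'"
                    )
                if (sp, gene) in seen:
                    raise FormatError(
                        f"{name}: line {line_no}: duplicate member '{tok}' in group '{gid}'"
                    )
                seen.add((sp, gene))
                members.setdefault(sp, []).append(gene)
            groups.append(
                OrthoGroup(group_id=gid, members={k: tuple(v) for k, v in members.items()})
            )
    finally:
        if close:
            fh.close()
    return groups


def write_groups(groups: Iterable[OrthoGroup], path: Union[str, Path]) -> None:
    with _open_text(path, "wt") as fh:
        for g in groups:
            toks = [f"{sp}|{gene}" for sp in g.members for gene in g.members[sp]]
            fh.write(f"{g.group_id}: " + " ".join(toks) + "\n")


# ---------------------------------------------------------------------------
# AGP v2.1

_AGP_HEADER = "##agp-version\t2.1"


def write_agp(superscaffolds: Sequence, path: Union[str, Path]) -> None:
    """Write superscaffold composition as AGP v2.1.

    ``superscaffolds`` are duck-typed: each needs ``object_id``, an ordered
    ``placements`` list (``query_id``, ``orientation``, ``placed_length``)
    and a parallel ``gaps`` list of inter-placement gap lengths (one fewer
    than placements).  Gap lines use gap_type ``scaffold`` with linkage.
    """
    with _open_text(path, "wt") as fh:
        fh.write(_AGP_HEADER + "\n")
        for ss in superscaffolds:
            pos = 0  # 0-based cursor; AGP columns are 1-based inclusive
            part = 0
            for i, pl in enumerate(ss.placements):
                if i > 0:
                    gap = ss.gaps[i - 1]
                    part += 1
                    fh.write(
                        "\t".join(
                            [
                                ss.object_id,
                                str(pos + 1),
                                str(pos + gap),
                                str(part),
                                "N",
                                str(gap),
                                "scaffold",
                                "yes",
                                "align_genus",
                            ]
                        )
                        + "\n"
                    )
                    pos += gap
                part += 1
                fh.write(
                    "\t".join(
                        [
                            ss.object_id,
                            str(pos + 1),
                            str(pos + pl.placed_length),
                            str(part),
                            "W",
                            pl.query_id,
                            "1",
                            str(pl.placed_length),
                            pl.orientation,
                        ]
                    )
                    + "\n"
                )
                pos += pl.placed_length
            if hasattr(ss, "sequence") and ss.sequence is not None and len(ss.sequence) != pos:
                raise InternalError(
                    f"AGP coordinates for '{ss.object_id}' sum to {pos} "
                    f"but sequence length is {len(ss.sequence)}"
                )


def read_agp(path: Union[str, Path]) -> pd.DataFrame:
    """Read an AGP file into a DataFrame of component and gap rows."""
    rows = []
    with _open_text(path) as fh:
        for line_no, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 9:
                raise FormatError(f"{path}: line {line_no}: expected 9 AGP columns")
            rows.append(
                {
                    "object": f[0],
                    "object_beg": int(f[1]),
                    "object_end": int(f[2]),
                    "part_number": int(f[3]),
                    "component_type": f[4],
                    "f6": f[5],
                    "f7": f[6],
                    "f8": f[7],
                    "f9": f[8],
                }
            )
    return pd.DataFrame(rows)


def agp_to_fasta(agp: pd.DataFrame, components: Mapping[str, str]) -> list[SeqRecord]:
    """Rebuild object sequences from an AGP table plus component sequences.

    The independent reconstruction used to check that the FASTA and AGP
    writers agree.
    """
    out: list[SeqRecord] = []
    if agp.empty:
        return out
    for obj, sub in agp.groupby("object", sort=False):
        parts: list[str] = []
        cursor = 0
        for _, row in sub.sort_values("part_number").iterrows():
            if row.object_beg != cursor + 1:
                raise FormatError(
                    f"AGP object '{obj}': part {row.part_number} is not contiguous"
                )
            if row.component_type == "N":
                parts.append("N" * int(row.f6))
            elif row.component_type == "W":
                seq = components[row.f6][int(row.f7) - 1 : int(row.f8)]
                if row.f9 == "-":
                    seq = revcomp(seq)
                parts.append(seq)
            else:
                raise FormatError(f"AGP object '{obj}': unsupported component type {row.component_type}")
            cursor = int(row.object_end)
        out.append(SeqRecord(id=str(obj), sequence="".join(parts)))
    return out


# ---------------------------------------------------------------------------
# trees


def parse_newick(text_or_path: Union[str, Path]) -> dendropy.Tree:
    """Parse a newick string (or file) into a dendropy Tree.

    Duplicate leaf labels and unbalanced parentheses raise
    :class:`FormatError`.
    """
    if isinstance(text_or_path, Path) or (
        isinstance(text_or_path, str) and "\n" not in text_or_path and Path(str(text_or_path)).is_file()
    ):
        text = Path(text_or_path).read_text()
    else:
        text = str(text_or_path)
    if text.count("(") != text.count(")"):
        raise FormatError("newick: unbalanced parentheses")
    try:
        tree = dendropy.Tree.get(data=text, schema="newick")
    except Exception as exc:  # dendropy raises several parse error types
        raise FormatError(f"newick: {exc}") from exc
    labels = [lf.taxon.label for lf in tree.leaf_node_iter() if lf.taxon is not None]
    if len(labels) != len(set(labels)):
        dup = sorted({l for l in labels if labels.count(l) > 1})
        raise FormatError(f"newick: duplicate leaf labels {dup}")
    return tree


def write_newick(tree: dendropy.Tree) -> str:
    return tree.as_string(schema="newick", suppress_rooting=True).strip()


# ---------------------------------------------------------------------------
# tabular formats

GENE_MAP_COLUMNS = ["gene_id", "genome", "scaffold_id", "start", "end", "strand", "ordinal"]
CT_COLUMNS = ["sample", "gene", "replicate", "ct"]


def read_gene_map(path: Union[str, Path]) -> pd.DataFrame:
    """Read the 7-column gene position TSV (1-based inclusive coordinates)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in GENE_MAP_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: gene map missing columns {missing}")
    if (df["start"] > df["end"]).any():
        bad = df.index[df["start"] > df["end"]][0]
        raise FormatError(f"{path}: gene map row {bad}: start > end")
    for scaf, sub in df.groupby("scaffold_id"):
        if not sub["ordinal"].is_monotonic_increasing or sub["ordinal"].duplicated().any():
            raise FormatError(
                f"{path}: ordinals on scaffold '{scaf}' are not strictly increasing"
            )
    return df[GENE_MAP_COLUMNS]


def write_gene_map(df: pd.DataFrame, path: Union[str, Path]) -> None:
    df[GENE_MAP_COLUMNS].to_csv(path, sep="\t", index=False)


def read_ct_table(path: Union[str, Path]) -> pd.DataFrame:
    """Read the replicated Ct CSV (columns sample, gene, replicate, ct)."""
    df = pd.read_csv(path)
    missing = [c for c in CT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: Ct table missing columns {missing}")
    if (df["ct"] <= 0).any():
        raise DataError(f"{path}: Ct values must be positive cycle numbers")
    cols = CT_COLUMNS + (["experiment"] if "experiment" in df.columns else [])
    return df[cols]


def write_ct_table(df: pd.DataFrame, path: Union[str, Path]) -> None:
    df[CT_COLUMNS].to_csv(path, index=False)


def read_khist(path: Union[str, Path]) -> dict[int, int]:
    """Read a two-column 'multiplicity<TAB>count' histogram; '#' comments allowed."""
    counts: dict[int, int] = {}
    with _open_text(path) as fh:
        for line_no, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise FormatError(f"{path}: line {line_no}: expected 2 tab-separated columns")
            try:
                m, h = int(parts[0]), int(parts[1])
            except ValueError as exc:
                raise FormatError(f"{path}: line {line_no}: non-integer value") from exc
            if m < 1 or h < 0:
                raise FormatError(f"{path}: line {line_no}: multiplicity/count out of range")
            if m in counts:
                raise FormatError(f"{path}: line {line_no}: duplicate multiplicity {m}")
            counts[m] = h
    return counts


def write_khist(counts: Mapping[int, int], path: Union[str, Path]) -> None:
    with _open_text(path, "wt") as fh:
        fh.write("#multiplicity\tcount\n")
        for m in sorted(counts):
            fh.write(f"{m}\t{counts[m]}\n")
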