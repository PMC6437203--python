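"""Readers and writers for the plain-text formats the pipeline touches.

Microsatellite genotypes travel as Genepop files (the de facto interchange
format for multi-allelic genotype data), mtDNA control-region haplotypes as
aligned FASTA, time series as CSV, and dendrograms as Newick.  All readers
reject malformed input with a descriptive error rather than coercing it;
all writers produce files their own readers round-trip bit-compatibly.
"""
from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO

#: allele code used for a missing gene copy inside a GenotypeTable
MISSING = 0

_ALLOWED_BASES = set("ACGTN-")


class ParseError(ValueError):
    """Raised when an input file violates its format contract."""


# ---------------------------------------------------------------------------
# Genotype container
# ---------------------------------------------------------------------------

@dataclass
class GenotypeTable:
    """Diploid multilocus genotypes with population labels.

    ``genotypes`` has shape ``(n_individuals, n_loci, 2)``; allele codes are
    positive integers, with 0 meaning a missing gene copy.  A genotype is
    treated as an unordered pair; both copies are 0 when the locus failed for
    that fish.
    """

    individual_ids: list[str]
    populations: list[str]
    locus_names: list[str]
    genotypes: np.ndarray

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=int)
        n = len(self.individual_ids)
        if len(self.populations) != n:
            raise ValueError("one population label per individual required")
        if not self.locus_names:
            raise ValueError("at least one locus required")
        if any(not p for p in self.populations):
            raise ValueError("population labels must be non-empty")
        if self.genotypes.shape != (n, len(self.locus_names), 2):
            raise ValueError(
                f"genotype array shape {self.genotypes.shape} does not match "
                f"{n} individuals x {len(self.locus_names)} loci x 2"
            )
        if (self.genotypes < 0).any():
            raise ValueError("allele codes must be non-negative integers")
        # half-missing genotypes are normalized to fully missing
        half = (self.genotypes == MISSING).any(axis=2) & (
            self.genotypes != MISSING
        ).any(axis=2)
        if half.any():
            self.genotypes = self.genotypes.copy()
            self.genotypes[half] = MISSING

    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)

    @property
    def n_loci(self) -> int:
        return len(self.locus_names)

    def population_names(self) -> list[str]:
        """Unique population labels in order of first appearance."""
        seen: dict[str, None] = {}
        for p in self.populations:
            seen.setdefault(p)
        return list(seen)

    def subset(self, populations: list[str] | str) -> "GenotypeTable":
        if isinstance(populations, str):
            populations = [populations]
        keep = [i for i, p in enumerate(self.populations) if p in populations]
        if not keep:
            raise ValueError(f"no individuals in populations {populations!r}")
        return GenotypeTable(
            [self.individual_ids[i] for i in keep],
            [self.populations[i] for i in keep],
            list(self.locus_names),
            self.genotypes[keep],
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeTable):
            return NotImplemented
        if (
            self.individual_ids != other.individual_ids
            or self.populations != other.populations
            or self.locus_names != other.locus_names
        ):
            return False
        # genotype pairs are unordered
        return bool(
            (np.sort(self.genotypes, axis=2) == np.sort(other.genotypes, axis=2)).all()
        )


# ---------------------------------------------------------------------------
# Genepop
# ---------------------------------------------------------------------------

def _split_genotype_token(token: str, lineno: int) -> tuple[int, int]:
    if not token.isdigit():
        raise ParseError(f"line {lineno}: non-numeric genotype token {token!r}")
    if len(token) == 4:
        a, b = int(token[:2]), int(token[2:])
    elif len(token) == 6:
        a, b = int(token[:3]), int(token[3:])
    else:
        raise ParseError(
            f"line {lineno}: genotype token {token!r} is neither 4 nor 6 digits"
        )
    return a, b


def read_genepop(path) -> GenotypeTable:
    """Parse a Genepop file into a :class:`GenotypeTable`.

    Dialect: first line is a title; locus names follow one per line (a single
    comma-separated line is also accepted); blocks are delimited by a
    case-insensitive ``Pop`` line; individual rows are ``id , tok tok ...``
    with 2- or 3-digit allele encodings auto-detected per token.  ``0``,
    ``00`` and ``000`` encode missing alleles.  The format carries no
    explicit population names, so each block is labelled by the common
    prefix of its individual ids up to the last underscore (the usual
    ``<sample>_<number>`` naming), falling back to ``Pop1``, ``Pop2``, ...
    when that yields nothing usable or duplicates.
    """
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise ParseError("empty file")
    # locus section
    locus_names: list[str] = []
    i = 1
    while i < len(lines):
        line = lines[i].strip()
        if line.lower() == "pop":
            break
        if line:
            if "," in line:
                locus_names.extend(t.strip() for t in line.split(",") if t.strip())
            else:
                locus_names.append(line)
        i += 1
    if not locus_names:
        raise ParseError("no locus names before the first Pop line")
    if i >= len(lines):
        raise ParseError("no Pop line found")

    blocks: list[list[tuple[str, list[tuple[int, int]], int]]] = []
    current: list[tuple[str, list[tuple[int, int]], int]] | None = None
    for lineno0 in range(i, len(lines)):
        raw = lines[lineno0]
        lineno = lineno0 + 1
        line = raw.strip()
        if not line:
            continue
        if line.lower() == "pop":
            if current is not None and not current:
                raise ParseError(f"line {lineno}: empty Pop block")
            if current is not None:
                blocks.append(current)
            current = []
            continue
        assert current is not None
        if "," not in line:
            raise ParseError(f"line {lineno}: expected 'id , genotypes', no comma")
        ind_id, geno_part = line.split(",", 1)
        tokens = geno_part.split()
        if len(tokens) != len(locus_names):
            raise ParseError(
                f"line {lineno}: {len(tokens)} genotypes for "
                f"{len(locus_names)} loci"
            )
        pairs = [_split_genotype_token(t, lineno) for t in tokens]
        current.append((ind_id.strip(), pairs, lineno))
    if current is None or not current:
        raise ParseError("empty Pop block at end of file")
    blocks.append(current)

    ids: list[str] = []
    pops: list[str] = []
    genos: list[list[tuple[int, int]]] = []
    labels: list[str] = []
    import os.path

    for b, block in enumerate(blocks):
        prefix = os.path.commonprefix([ind_id for ind_id, _, _ in block])
        label = prefix[: prefix.rfind("_")] if "_" in prefix else ""
        labels.append(label or f"Pop{b + 1}")
    if len(set(labels)) != len(labels):
        labels = [f"Pop{b + 1}" for b in range(len(blocks))]
    for label, block in zip(labels, blocks):
        for ind_id, pairs, _ in block:
            ids.append(ind_id)
            pops.append(label)
            genos.append(pairs)
    return GenotypeTable(ids, pops, locus_names, np.array(genos, dtype=int))


def write_genepop(table: GenotypeTable, path, title: str = "seabream export",
                  digits: int = 3) -> None:
    """Write a :class:`GenotypeTable` as a Genepop file.

    Alleles are zero-padded to ``digits`` (3 by default, the microsatellite
    convention); missing gene copies become ``000``.
    """
    if digits not in (2, 3):
        raise ValueError("digits must be 2 or 3")
    if int(table.genotypes.max(initial=0)) >= 10 ** digits:
        raise ValueError(f"allele codes do not fit in {digits} digits")
    out = [title]
    out.extend(table.locus_names)
    for pop in table.population_names():
        out.append("Pop")
        for i in range(table.n_individuals):
            if table.populations[i] != pop:
                continue
            toks = [
                f"{a:0{digits}d}{b:0{digits}d}" for a, b in table.genotypes[i]
            ]
            out.append(f"{table.individual_ids[i]} ,  " + " ".join(toks))
    with open(path, "w") as fh:
        fh.write("\n".join(out) + "\n")


# ---------------------------------------------------------------------------
# FASTA haplotype alignments
# ---------------------------------------------------------------------------

@dataclass
class HaplotypeAlignment:
    """Aligned mtDNA haplotype sequences with per-sequence population labels."""

    ids: list[str]
    populations: list[str]
    sequences: list[str]

    def __post_init__(self) -> None:
        if not self.sequences:
            raise ValueError("empty alignment")
        L = len(self.sequences[0])
        for sid, seq in zip(self.ids, self.sequences):
            if len(seq) != L:
                raise ParseError(
                    f"sequence {sid!r} has length {len(seq)}, expected {L}"
                )
            bad = set(seq) - _ALLOWED_BASES
            if bad:
                raise ParseError(
                    f"sequence {sid!r} contains disallowed character(s) "
                    f"{sorted(bad)!r}"
                )

    @property
    def length(self) -> int:
        return len(self.sequences[0])

    @property
    def n_sequences(self) -> int:
        return len(self.sequences)


def read_fasta_alignment(path, pop_pattern: str = r"^([^_]+)") -> HaplotypeAlignment:
    """Read an aligned FASTA file.

    ``pop_pattern`` is a regex whose first group extracts the population
    label from each record id (default: everything before the first
    underscore).  Records are uppercased; unequal lengths or characters
    outside ``ACGTN-`` are rejected naming the offender.
    """
    pat = re.compile(pop_pattern)
    ids, pops, seqs = [], [], []
    for rec in SeqIO.parse(str(path), "fasta"):
        ids.append(rec.id)
        m = pat.search(rec.id)
        pops.append(m.group(1) if m else rec.id)
        seqs.append(str(rec.seq).upper())
    if not ids:
        raise ParseError(f"no FASTA records in {path}")
    return HaplotypeAlignment(ids, pops, seqs)


@dataclass
class HaplotypeCounts:
    """Haplotype counts per population after complete deletion of gapped sites.

    ``counts`` is haplotype x population; ``kept_sites`` are the 1-based
    alignment positions that survived (no gap or N in any sequence).
    """

    counts: pd.DataFrame
    kept_sites: np.ndarray

    def totals(self) -> pd.Series:
        return self.counts.sum(axis=1)


def collapse_haplotypes(aln: HaplotypeAlignment) -> HaplotypeCounts:
    """Collapse aligned sequences into haplotypes.

    Sites carrying a gap or an N in *any* sequence are excluded alignment-wide
    (complete deletion); the remaining strings are grouped by identity and
    counted per population.
    """
    mat = np.array([list(s) for s in aln.sequences])
    keep = ~np.isin(mat, ["-", "N"]).any(axis=0)
    if not keep.any():
        raise ValueError("complete deletion removed every alignment site")
    kept_sites = np.flatnonzero(keep) + 1  # 1-based positions
    cores = ["".join(row) for row in mat[:, keep]]
    order: dict[str, int] = {}
    for c in cores:
        order.setdefault(c, len(order))
    pops = list(dict.fromkeys(aln.populations))
    counts = np.zeros((len(order), len(pops)), dtype=int)
    pop_idx = {p: j for j, p in enumerate(pops)}
    for core, pop in zip(cores, aln.populations):
        counts[order[core], pop_idx[pop]] += 1
    index = [f"H{i + 1:03d}" for i in range(len(order))]
    df = pd.DataFrame(counts, index=index, columns=pops)
    df.attrs["haplotype_sequences"] = {f"H{i + 1:03d}": c for c, i in order.items()}
    return HaplotypeCounts(df, kept_sites)


# ---------------------------------------------------------------------------
# Time series CSV
# ---------------------------------------------------------------------------

def read_time_series(path) -> pd.DataFrame:
    """Read an annual time-series CSV with a ``year`` column.

    Years must be strictly increasing integers with no duplicates.
    """
    df = pd.read_csv(path)
    if "year" not in df.columns:
        raise ParseError(f"{path}: no 'year' column")
    years = df["year"].to_numpy()
    if not np.issubdtype(years.dtype, np.integer):
        raise ParseError(f"{path}: 'year' column must be integer")
    if (np.diff(years) <= 0).any():
        raise ParseError(f"{path}: years must be strictly increasing")
    return df


def write_time_series(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Newick
# ---------------------------------------------------------------------------

def _quote_label(label: str) -> str:
    if re.search(r"[\s,():;'\[\]]", label):
        return "'" + label.replace("'", "''") + "'"
    return label


def tree_to_newick(tree) -> str:
    """Serialize a rooted tree with node heights as a Newick string.

    Branch lengths are parent height minus child height, so an ultrametric
    tree yields equal root-to-leaf path lengths.
    """

    def render(node, parent_height: float) -> str:
        bl = parent_height - node.height
        if node.is_leaf():
            return f"{_quote_label(node.label)}:{bl:.10g}"
        inner = ",".join(render(c, node.height) for c in node.children)
        return f"({inner}):{bl:.10g}"

    root = tree.root
    if root.is_leaf():
        return f"{_quote_label(root.label)};"
    inner = ",".join(render(c, root.height) for c in root.children)
    return f"({inner});"


def write_newick(tree, path) -> None:
    with open(path, "w") as fh:
        fh.write(tree_to_newick(tree) + "\n")
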