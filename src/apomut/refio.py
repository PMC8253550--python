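"""Reference I/O and trinucleotide-context machinery.

All internal coordinates are 0-based, half-open.  Inputs in 1-based dialects
(MAF-lite, GFF3) are converted at the boundary.  Substitution contexts are
pyrimidine-oriented: every SBS is expressed on the strand whose central base
is C or T, which is the convention under which the APOBEC signature (TCN)
is defined.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO

log = logging.getLogger(__name__)

# base encoding: A=0 C=1 G=2 T=3 N=4; complement of b<4 is 3-b
_BASE_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _BASE_CODE[ord(_b)] = _i
    _BASE_CODE[ord(_b.lower())] = _i
_BASES = "ACGT"
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def revcomp(seq: str) -> str:
    return "".join(_COMP[b] for b in reversed(seq))


def trimer_code(trimer: str) -> int:
    """Integer code of a 3-mer over ACGT (16*left + 4*center + right)."""
    a, b, c = (_BASES.index(x) for x in trimer)
    return 16 * a + 4 * b + c


def code_to_trimer(code: int) -> str:
    return _BASES[code >> 4] + _BASES[(code >> 2) & 3] + _BASES[code & 3]


def _revcomp_code(code: int) -> int:
    a, b, c = code >> 4, (code >> 2) & 3, code & 3
    return 16 * (3 - c) + 4 * (3 - b) + (3 - a)


ALL_TRIMERS = [code_to_trimer(c) for c in range(64)]
#: pyrimidine-centered trinucleotides (central C or T), the 32 context rows
PYR_TRIMERS = [t for t in ALL_TRIMERS if t[1] in "CT"]


def motif_class_trimers(motif_class: str) -> list[str]:
    """Expand a motif-class name to pyrimidine-strand 3-mers.

    Recognized classes: TCN, TCW, TCS, NCN (all cytosine-centered),
    NTN (all thymine-centered), non_tcn_c, or a concrete 3-mer with a
    central pyrimidine.
    """
    ncn = [t for t in ALL_TRIMERS if t[1] == "C"]
    tcn = [t for t in ncn if t[0] == "T"]
    table = {
        "TCN": tcn,
        "TCW": ["TCA", "TCT"],
        "TCS": ["TCC", "TCG"],
        "NCN": ncn,
        "NTN": [t for t in ALL_TRIMERS if t[1] == "T"],
        "non_tcn_c": [t for t in ncn if t not in tcn],
    }
    if motif_class in table:
        return table[motif_class]
    if len(motif_class) == 3 and set(motif_class) <= set(_BASES) and motif_class[1] in "CT":
        return [motif_class]
    raise ValueError(f"unknown motif class {motif_class!r}")


def motif_luts(motif_class: str) -> tuple[np.ndarray, np.ndarray]:
    """(plus, minus) boolean lookup tables over 3-mer codes.

    ``plus[code]`` is True when the plus-strand 3-mer carries the motif with
    its central pyrimidine on the plus strand; ``minus`` when the reverse
    complement does (central purine on the plus strand).
    """
    plus = np.zeros(64, dtype=bool)
    minus = np.zeros(64, dtype=bool)
    for t in motif_class_trimers(motif_class):
        c = trimer_code(t)
        plus[c] = True
        minus[_revcomp_code(c)] = True
    return plus, minus


@dataclass
class GenomeContext:
    """In-memory genome with cached trinucleotide-code arrays.

    ``trimer_codes(chrom)[p]`` is the code of the 3-mer centered at p, or -1
    where the window leaves the chromosome or touches an N.
    """

    chroms: dict[str, str]
    _enc: dict[str, np.ndarray] = field(default_factory=dict, repr=False)
    _codes: dict[str, np.ndarray] = field(default_factory=dict, repr=False)

    @property
    def chrom_names(self) -> list[str]:
        return list(self.chroms)

    def length(self, chrom: str) -> int:
        return len(self.chroms[chrom])

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.chroms.values())

    def base(self, chrom: str, pos: int) -> str:
        if not 0 <= pos < len(self.chroms[chrom]):
            raise IndexError(f"position {pos} outside {chrom}")
        return self.chroms[chrom][pos]

    def encoded(self, chrom: str) -> np.ndarray:
        if chrom not in self._enc:
            self._enc[chrom] = _BASE_CODE[np.frombuffer(self.chroms[chrom].encode(), dtype=np.uint8)]
        return self._enc[chrom]

    def trimer_codes(self, chrom: str) -> np.ndarray:
        if chrom not in self._codes:
            e = self.encoded(chrom).astype(np.int16)
            codes = np.full(e.shape, -1, dtype=np.int16)
            if len(e) >= 3:
                valid = (e[:-2] < 4) & (e[1:-1] < 4) & (e[2:] < 4)
                mid = 16 * e[:-2] + 4 * e[1:-1] + e[2:]
                codes[1:-1] = np.where(valid, mid, -1)
            self._codes[chrom] = codes
        return self._codes[chrom]


def read_fasta(path: str) -> GenomeContext:
    """Read a FASTA file; sequences are uppercased, soft-masking ignored."""
    chroms: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in chroms:
            raise ValueError(f"duplicate chromosome name {rec.id!r}")
        seq = str(rec.seq).upper()
        bad = set(seq) - set("ACGTN")
        if bad:
            pos = min(seq.index(b) for b in bad)
            raise ValueError(f"non-ACGTN character {seq[pos]!r} in {rec.id} at position {pos}")
        chroms[rec.id] = seq
    log.info("read_fasta: %d sequences, %d bp", len(chroms), sum(map(len, chroms.values())))
    return GenomeContext(chroms)


def write_fasta(genome: GenomeContext, path: str, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.chroms.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# pyrimidine orientation


def pyrimidine_normalize(genome: GenomeContext, chrom: str, pos: int, ref: str, alt: str):
    """Orient an SBS on the strand whose mutated base is a pyrimidine.

    Returns ``(pyr_context, pyr_alt, pyr_strand)``; ``pyr_context`` is None
    when the 3-mer window leaves the chromosome or contains an N (the record
    is then excluded from motif-based statistics).
    """
    if genome.base(chrom, pos) != ref:
        raise ValueError(f"ref {ref} does not match genome at {chrom}:{pos}")
    code = genome.trimer_codes(chrom)[pos]
    if ref in "CT":
        strand = "+"
        ctx = None if code < 0 else code_to_trimer(code)
        return ctx, alt, strand
    strand = "-"
    ctx = None if code < 0 else code_to_trimer(_revcomp_code(int(code)))
    return ctx, _COMP[alt], strand


def annotate_mutations(df: pd.DataFrame, genome: GenomeContext, strict: bool = True):
    """Vectorized context annotation for a (sample, chrom, pos, ref, alt) frame.

    Adds pyr_context / pyr_alt / pyr_strand / context_ok columns; ``pos`` is
    0-based.  Returns (frame, counters).
    """
    counters = {"ref_mismatch": 0}
    parts = []
    for chrom, sub in df.groupby("chrom", sort=False):
        codes = genome.trimer_codes(chrom)
        enc = genome.encoded(chrom)
        pos = sub["pos"].to_numpy()
        if pos.min() < 0 or pos.max() >= len(enc):
            raise ValueError(f"position outside chromosome {chrom}")
        ref_code = np.array([_BASES.index(r) if r in _BASES else 4 for r in sub["ref"]])
        ok_ref = enc[pos] == ref_code
        if not ok_ref.all():
            if strict:
                bad = sub[~ok_ref].iloc[0]
                raise ValueError(
                    f"ref mismatch at {chrom}:{bad['pos'] + 1} (file {bad['ref']}, genome {genome.base(chrom, int(bad['pos']))})"
                )
            counters["ref_mismatch"] += int((~ok_ref).sum())
            sub = sub[ok_ref]
            pos = pos[ok_ref]
        c = codes[pos].astype(int)
        is_pyr = np.isin(sub["ref"].to_numpy(), list("CT"))
        ctx_ok = c >= 0
        ctx = np.array(
            [
                (code_to_trimer(cc) if p else code_to_trimer(_revcomp_code(cc))) if cc >= 0 else ""
                for cc, p in zip(c, is_pyr)
            ]
        )
        alt = sub["alt"].to_numpy()
        pyr_alt = np.where(is_pyr, alt, [_COMP[a] for a in alt])
        out = sub.copy()
        out["pyr_context"] = ctx
        out["pyr_alt"] = pyr_alt
        out["pyr_strand"] = np.where(is_pyr, "+", "-")
        out["context_ok"] = ctx_ok
        parts.append(out)
    res = pd.concat(parts, ignore_index=True) if parts else df.assign(
        pyr_context="", pyr_alt="", pyr_strand="+", context_ok=False
    )
    return res, counters


def read_mutations(path: str, genome: GenomeContext, strict: bool = True, fmt: str = "maf", sample: str | None = None):
    """Read a somatic SBS catalog.

    ``fmt='maf'``: TSV with header sample, chrom, pos (1-based), ref, alt.
    ``fmt='vcf'``: minimal VCF; all records attributed to ``sample``.
    Indels (len(ref) != 1 or len(alt) != 1) are dropped and counted.
    """
    if fmt == "maf":
        df = pd.read_csv(path, sep="\t", dtype={"sample": str, "chrom": str, "ref": str, "alt": str})
        missing = {"sample", "chrom", "pos", "ref", "alt"} - set(df.columns)
        if missing:
            raise ValueError(f"missing columns {sorted(missing)}")
    elif fmt == "vcf":
        rows = []
        sid = sample or "sample1"
        with open(path) as fh:
            for line in fh:
                if line.startswith("#"):
                    continue
                f = line.rstrip("\n").split("\t")
                rows.append((sid, f[0], int(f[1]), f[3], f[4]))
        df = pd.DataFrame(rows, columns=["sample", "chrom", "pos", "ref", "alt"])
    else:
        raise ValueError(f"unknown format {fmt!r}")
    n_in = len(df)
    is_snv = (df["ref"].str.len() == 1) & (df["alt"].str.len() == 1)
    counters = {"rows_in": n_in, "indels_dropped": int((~is_snv).sum())}
    df = df[is_snv].copy()
    df["pos"] = df["pos"].astype(np.int64) - 1  # to 0-based
    if (df["ref"] == df["alt"]).any():
        raise ValueError("record with alt == ref")
    df, c2 = annotate_mutations(df, genome, strict=strict)
    counters.update(c2)
    counters["rows_kept"] = len(df)
    log.info("read_mutations: %s", counters)
    return df.reset_index(drop=True), counters


# ---------------------------------------------------------------------------
# interval formats


def _check_sorted_nonoverlapping(df: pd.DataFrame) -> pd.DataFrame:
    df = df.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)
    for chrom, sub in df.groupby("chrom", sort=False):
        s, e = sub["start"].to_numpy(), sub["end"].to_numpy()
        if (s >= e).any():
            raise ValueError(f"empty or inverted interval on {chrom}")
        if (s[1:] < e[:-1]).any():
            raise ValueError(f"overlapping intervals on {chrom}")
    return df


def read_bedgraph(path: str) -> pd.DataFrame:
    """Read a 4-column bedGraph into a sorted, non-overlapping segment frame."""
    try:
        df = pd.read_csv(
            path, sep=r"\s+", header=None, comment="#",
            names=["chrom", "start", "end", "value"],
            dtype={"chrom": str, "start": np.int64, "end": np.int64, "value": float},
        )
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=["chrom", "start", "end", "value"])
    if df["value"].isna().any():
        raise ValueError("non-numeric value in bedGraph")
    return _check_sorted_nonoverlapping(df)


def read_genes(path: str, dialect: str | None = None) -> pd.DataFrame:
    """Read gene models from BED6 or GFF3 into a 0-based half-open frame.

    Strand is required (sense/antisense assignment depends on it).
    """
    if dialect is None:
        dialect = "gff3" if str(path).endswith((".gff", ".gff3")) else "bed6"
    rows = []
    if dialect == "bed6":
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith(("#", "track")):
                    continue
                f = line.split()
                if len(f) < 6:
                    raise ValueError("BED6 requires 6 columns (strand missing?)")
                rows.append((f[3], f[0], int(f[1]), int(f[2]), f[5]))
    elif dialect == "gff3":
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith("#"):
                    continue
                f = line.rstrip("\n").split("\t")
                if f[2] != "gene":
                    continue
                attrs = dict(kv.split("=", 1) for kv in f[8].split(";") if "=" in kv)
                gid = attrs.get("ID") or attrs.get("gene_id")
                rows.append((gid, f[0], int(f[3]) - 1, int(f[4]), f[6]))
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    df = pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "strand"])
    if df["gene_id"].duplicated().any():
        dup = df.loc[df["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise ValueError(f"duplicate gene id {dup!r}")
    if not set(df["strand"]) <= {"+", "-"}:
        raise ValueError("gene without strand (+/- required)")
    log.info("read_genes: %d genes", len(df))
    return df.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)


# ---------------------------------------------------------------------------
# motif counting


def _as_interval_frame(intervals, genome: GenomeContext) -> pd.DataFrame:
    if intervals is None:
        return pd.DataFrame(
            {"chrom": genome.chrom_names, "start": 0, "end": [genome.length(c) for c in genome.chrom_names]}
        )
    if isinstance(intervals, pd.DataFrame):
        return intervals[["chrom", "start", "end"]].copy()
    return pd.DataFrame(intervals, columns=["chrom", "start", "end"])


def count_motifs(genome: GenomeContext, intervals=None, motif_class: str = "TCN",
                 per_strand: bool = False, per_interval: bool = False):
    """Count motif occurrences whose central base falls inside intervals.

    Motifs are counted on both strands (a TGA on the plus strand is a TCA on
    the minus strand).  Overlapping input intervals are rejected, so no site
    is double-counted.  With ``per_strand`` the two orientations are kept
    separate; with ``per_interval`` the per-row counts are returned in input
    order alongside the frame.
    """
    iv = _as_interval_frame(intervals, genome)
    iv["_order"] = np.arange(len(iv))
    _check_sorted_nonoverlapping(iv)
    plus_lut, minus_lut = motif_luts(motif_class)
    plus = np.zeros(len(iv), dtype=np.int64)
    minus = np.zeros(len(iv), dtype=np.int64)
    for chrom, sub in iv.groupby("chrom", sort=False):
        codes = genome.trimer_codes(chrom)
        if sub["end"].max() > len(codes) or sub["start"].min() < 0:
            raise ValueError(f"interval outside chromosome {chrom}")
        pm = np.where(codes >= 0, plus_lut[codes], False)
        mm = np.where(codes >= 0, minus_lut[codes], False)
        # int32 scans: counts stay far below 2^31 and the scan is much faster
        cp = np.concatenate(([0], np.cumsum(pm, dtype=np.int32)))
        cm = np.concatenate(([0], np.cumsum(mm, dtype=np.int32)))
        s, e = sub["start"].to_numpy(), sub["end"].to_numpy()
        plus[sub.index] = cp[e] - cp[s]
        minus[sub.index] = cm[e] - cm[s]
    order = iv["_order"].to_numpy()
    inv = np.argsort(order)
    plus, minus = plus[inv], minus[inv]
    if per_interval:
        return (plus, minus) if per_strand else plus + minus
    if per_strand:
        return int(plus.sum()), int(minus.sum())
    return int(plus.sum() + minus.sum())


# ---------------------------------------------------------------------------
# reverse-complement transforms (strand-symmetry checks)


def mirror_genome(genome: GenomeContext) -> GenomeContext:
    return GenomeContext({c: revcomp(s) for c, s in genome.chroms.items()})


def mirror_mutations(df: pd.DataFrame, genome: GenomeContext) -> pd.DataFrame:
    """Map a catalog onto the reverse-complemented genome (coordinates and alleles)."""
    out = df.copy()
    lengths = out["chrom"].map({c: genome.length(c) for c in genome.chrom_names})
    out["pos"] = lengths - 1 - out["pos"]
    out["ref"] = [_COMP[b] for b in out["ref"]]
    out["alt"] = [_COMP[b] for b in out["alt"]]
    return out.drop(columns=[c for c in ("pyr_context", "pyr_alt", "pyr_strand", "context_ok") if c in out])


def mirror_intervals(df: pd.DataFrame, genome: GenomeContext) -> pd.DataFrame:
    out = df.copy()
    lengths = out["chrom"].map({c: genome.length(c) for c in genome.chrom_names})
    start = lengths - out["end"]
    out["end"] = lengths - out["start"]
    out["start"] = start
    if "strand" in out:
        out["strand"] = out["strand"].map({"+": "-", "-": "+"})
    return out.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)
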