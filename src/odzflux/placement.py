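"""Quantification of phylogenetically placed metagenomic reads.

Short reads recruited to marker genes (psbD, rRNA ITS, rpoB, viral DNA
polymerase) and placed on fixed reference trees arrive here as flat
placement records (or jplace JSON plus an edge→clade map).  The pipeline:

1. **Filter** — placements with a pendant "branchlength" above 2.0 are
   discarded as belonging to other genes; reads shorter than 100 nt
   (33 aa) are discarded as untrustworthy.
2. **Normalize** — counts are divided by library size and reference gene
   length and multiplied by 100, making markers of different length and
   libraries of different depth comparable.
3. **Copy-number correct** — multi-copy markers (the rRNA ITS in
   Synechococcus, Prochlorococcus LLIV/V, and NC1 genomes, 2 copies) are
   divided by their per-genome copy number.

On top of the resulting abundance table sit the derived statistics:
virus-to-host marker ratios (cyanophage DNA polymerase / cyanobacterial
rpoB), within-gene composition fractions, cross-sample proportion
comparisons against the 1:1 line, and peptide-sharing fractions for
metaproteomic samples.
"""

from __future__ import annotations

import json
import warnings
from collections import defaultdict
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PlacementRead",
    "MetagenomeSample",
    "GeneMeta",
    "FilterConfig",
    "AbundanceTable",
    "PeptideObservation",
    "filter_reads",
    "normalize_abundance",
    "virus_host_ratio",
    "composition_fractions",
    "compare_proportions",
    "peptide_overlap",
    "shared_fraction",
    "read_jplace",
    "read_placement_tsv",
]

#: ITS copy-number exceptions: these genomes carry two rRNA operons.
TWO_COPY_ITS_CLADES = ("Synechococcus", "Prochlorococcus_LLIV_V", "NC1")


@dataclass(frozen=True)
class PlacementRead:
    """One placed read (a merged read pair counts as one record)."""

    read_id: str
    gene: str
    clade: str
    branch_length: float  # pendant branch, substitutions/site
    read_len: int  # nt after trimming
    sample_id: str
    weight: float = 1.0  # like_weight_ratio of the chosen placement
    paired: bool = False

    def __post_init__(self) -> None:
        if self.branch_length < 0:
            raise ValueError("branch length must be ≥ 0")
        if self.read_len <= 0:
            raise ValueError("read length must be > 0")


@dataclass(frozen=True)
class MetagenomeSample:
    sample_id: str
    library_size: int  # total sequences in the metagenome
    size_fraction: str = ">0.2um"
    depth: float = 0.0  # m

    def __post_init__(self) -> None:
        if self.library_size <= 0:
            raise ValueError("library size must be > 0")


@dataclass(frozen=True)
class GeneMeta:
    """Reference-gene metadata used by normalization."""

    gene: str
    ref_length: float  # alignment reference length
    length_unit: str = "aa"  # "aa" for protein markers, "nt" for ITS
    copy_number: Mapping[str, float] = field(default_factory=dict)  # clade → copies

    def __post_init__(self) -> None:
        if self.ref_length <= 0:
            raise ValueError("gene reference length must be > 0")
        for clade, cn in self.copy_number.items():
            if cn < 1:
                raise ValueError(f"copy number < 1 for clade {clade!r}")

    def copies(self, clade: str) -> float:
        return float(self.copy_number.get(clade, 1.0))


@dataclass(frozen=True)
class FilterConfig:
    """Placement quality filters.

    ``max_branch_length`` removes reads whose pendant branch exceeds the
    threshold (2.0 — such reads belong to other genes).  Minimum read
    lengths are 100 nt / 33 aa.  The e-value cutoff (10⁻⁵) was applied
    upstream during read recruitment; it is recorded here as provenance
    only.
    """

    max_branch_length: float = 2.0
    min_read_len_nt: int = 100
    min_read_len_aa: int = 33
    max_evalue_exponent: float = -5.0


@dataclass
class AbundanceTable:
    """Long-format abundances: one row per (sample, gene, clade).

    ``abundance`` is reads / library size / gene length × 100, after
    copy-number division; ``raw_count`` keeps the unnormalized integer.
    """

    data: pd.DataFrame  # columns: sample_id, gene, clade, raw_count, abundance

    def slice(self, gene: str, sample_id: str) -> pd.DataFrame:
        d = self.data
        return d[(d["gene"] == gene) & (d["sample_id"] == sample_id)]


@dataclass(frozen=True)
class PeptideObservation:
    sample_id: str
    peptide: str
    taxon: str = ""

    def __post_init__(self) -> None:
        if not self.peptide:
            raise ValueError("peptide sequence must be non-empty")


def filter_reads(
    reads: Sequence[PlacementRead], cfg: FilterConfig | None = None
) -> tuple[list[PlacementRead], list[PlacementRead], float]:
    """Apply branch-length and read-length filters.

    Returns ``(kept, removed, removed_fraction)``; kept and removed
    partition the input exactly.  Length thresholds are in nt; protein
    markers use 3 nt per aa.
    """
    cfg = cfg or FilterConfig()
    kept: list[PlacementRead] = []
    removed: list[PlacementRead] = []
    for r in reads:
        ok = r.branch_length <= cfg.max_branch_length and r.read_len >= cfg.min_read_len_nt
        (kept if ok else removed).append(r)
    frac = len(removed) / len(reads) if reads else 0.0
    return kept, removed, frac


def _dedupe_pairs(reads: Sequence[PlacementRead]) -> list[PlacementRead]:
    """Collapse paired records sharing a read id to a single placement.

    Ties on placement weight are broken deterministically toward the
    lexicographically smaller clade label with a warning (a proxy for the
    more basal assignment when labels encode depth).
    """
    by_id: dict[tuple[str, str, str], list[PlacementRead]] = defaultdict(list)
    for r in reads:
        by_id[(r.sample_id, r.gene, r.read_id)].append(r)
    out: list[PlacementRead] = []
    for grp in by_id.values():
        if len(grp) == 1:
            out.append(grp[0])
            continue
        best_w = max(r.weight for r in grp)
        best = sorted((r for r in grp if r.weight == best_w), key=lambda r: r.clade)
        if len(best) > 1:
            warnings.warn(
                f"read {best[0].read_id!r}: placement-weight tie among "
                f"{[r.clade for r in best]}; keeping {best[0].clade!r}",
                stacklevel=2,
            )
        out.append(best[0])
    return out


def normalize_abundance(
    reads: Sequence[PlacementRead],
    samples: Sequence[MetagenomeSample],
    genes: Sequence[GeneMeta],
) -> AbundanceTable:
    """Build the normalized, copy-number-corrected abundance table.

    abundance(sample, gene, clade) = count / (library_size · gene_length)
    × 100 / copy_number.  Reads whose sample or gene lacks metadata are a
    hard error listing every offender.
    """
    sample_map = {s.sample_id: s for s in samples}
    gene_map = {g.gene: g for g in genes}
    missing_s = sorted({r.sample_id for r in reads} - set(sample_map))
    missing_g = sorted({r.gene for r in reads} - set(gene_map))
    if missing_s or missing_g:
        raise KeyError(
            f"missing metadata — samples: {missing_s or 'none'}, genes: {missing_g or 'none'}"
        )

    counts: dict[tuple[str, str, str], int] = defaultdict(int)
    for r in _dedupe_pairs(reads):
        counts[(r.sample_id, r.gene, r.clade)] += 1

    rows = []
    for (sid, gene, clade), n in sorted(counts.items()):
        g = gene_map[gene]
        lib = sample_map[sid].library_size
        ab = n / (lib * g.ref_length) * 100.0 / g.copies(clade)
        rows.append(
            {
                "sample_id": sid,
                "gene": gene,
                "clade": clade,
                "raw_count": n,
                "abundance": ab,
            }
        )
    df = pd.DataFrame(
        rows, columns=["sample_id", "gene", "clade", "raw_count", "abundance"]
    )
    return AbundanceTable(df)


def virus_host_ratio(
    table: AbundanceTable,
    virus_gene: str,
    host_gene: str,
    sample_id: str,
) -> float | None:
    """Virus-to-host marker ratio for one sample.

    Length-normalized virus-marker abundance summed over viral clades over
    host-marker abundance summed over host clades (cyanophage DNA
    polymerase / cyanobacterial rpoB).  Returns None when the host marker
    is absent — the ratio is undefined, not infinite.
    """
    v = table.slice(virus_gene, sample_id)["abundance"].sum()
    h = table.slice(host_gene, sample_id)["abundance"].sum()
    if h == 0:
        return None
    return float(v / h)


def composition_fractions(
    table: AbundanceTable, gene: str, sample_id: str
) -> dict[str, float]:
    """Clade → fraction of normalized abundance within one gene and sample."""
    sl = table.slice(gene, sample_id)
    total = sl["abundance"].sum()
    if total <= 0:
        raise ValueError(f"no abundance for gene {gene!r} in sample {sample_id!r}")
    return dict(zip(sl["clade"], sl["abundance"] / total))


def compare_proportions(
    table: AbundanceTable, gene: str, sample_a: str, sample_b: str
) -> pd.DataFrame:
    """Clade-matched composition fractions of two samples vs the 1:1 line.

    Clades absent from one sample enter with fraction 0.  The returned frame
    carries ``max_abs_dev`` and ``rms_dev`` in ``attrs``.
    """
    fa = composition_fractions(table, gene, sample_a)
    fb = composition_fractions(table, gene, sample_b)
    clades = sorted(set(fa) | set(fb))
    df = pd.DataFrame(
        {
            "clade": clades,
            "fraction_a": [fa.get(c, 0.0) for c in clades],
            "fraction_b": [fb.get(c, 0.0) for c in clades],
        }
    )
    dev = (df["fraction_a"] - df["fraction_b"]).to_numpy()
    df.attrs["max_abs_dev"] = float(np.max(np.abs(dev))) if len(dev) else 0.0
    df.attrs["rms_dev"] = float(np.sqrt(np.mean(dev**2))) if len(dev) else 0.0
    return df


def peptide_overlap(
    obs: Iterable[PeptideObservation],
    focal_sample: str,
    other_samples: Sequence[str],
    taxon_filter: str | None = None,
) -> dict[frozenset[str], float]:
    """Venn-style sharing of a focal sample's peptides with other samples.

    For every subset of ``other_samples`` (including the empty one,
    peptides unique to the focal sample), the fraction of focal peptides
    found in exactly that subset.  Fractions sum to 1 over the partition.
    """
    if taxon_filter is not None:
        obs = [o for o in obs if o.taxon == taxon_filter]
    else:
        obs = list(obs)
    sets: dict[str, set[str]] = defaultdict(set)
    for o in obs:
        sets[o.sample_id].add(o.peptide)
    focal = sets.get(focal_sample, set())
    if not focal:
        raise ValueError(f"focal sample {focal_sample!r} has no peptides after filtering")
    out: dict[frozenset[str], float] = {}
    for r in range(len(other_samples) + 1):
        for subset in combinations(other_samples, r):
            in_these = set(focal)
            for s in subset:
                in_these &= sets.get(s, set())
            for s in other_samples:
                if s not in subset:
                    in_these -= sets.get(s, set())
            out[frozenset(subset)] = len(in_these) / len(focal)
    return out


def shared_fraction(
    obs: Iterable[PeptideObservation],
    focal_sample: str,
    other_sample: str,
    taxon_filter: str | None = None,
) -> float:
    """Fraction of focal-sample peptides also seen in ``other_sample``."""
    parts = peptide_overlap(obs, focal_sample, [other_sample], taxon_filter)
    return parts[frozenset([other_sample])]


def read_placement_tsv(path) -> list[PlacementRead]:
    """Read the flat placement dialect (read_id, gene, clade, branch_length,
    read_len_nt, sample_id [, weight, paired])."""
    df = pd.read_csv(path, sep="\t")
    required = {"read_id", "gene", "clade", "branch_length", "read_len_nt", "sample_id"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"placement TSV missing columns: {sorted(missing)}")
    return [
        PlacementRead(
            read_id=str(r.read_id),
            gene=str(r.gene),
            clade=str(r.clade),
            branch_length=float(r.branch_length),
            read_len=int(r.read_len_nt),
            sample_id=str(r.sample_id),
            weight=float(getattr(r, "weight", 1.0)),
            paired=bool(getattr(r, "paired", False)),
        )
        for r in df.itertuples(index=False)
    ]


def read_jplace(
    path,
    edge_to_clade: Mapping[int, str],
    gene: str,
    sample_id: str,
    read_lengths: Mapping[str, int] | None = None,
    default_read_len: int = 150,
) -> list[PlacementRead]:
    """Ingest a jplace file, mapping edge numbers to clades.

    Only the best placement (highest like_weight_ratio) per query is kept.
    jplace carries no read lengths, so they come from ``read_lengths`` or
    the default.
    """
    with open(path) as fh:
        doc = json.load(fh)
    fields = doc["fields"]
    i_edge = fields.index("edge_num")
    i_lwr = fields.index("like_weight_ratio")
    i_pend = fields.index("pendant_length")
    reads: list[PlacementRead] = []
    for placement in doc["placements"]:
        names = placement.get("n") or [nm[0] for nm in placement.get("nm", [])]
        best = max(placement["p"], key=lambda p: p[i_lwr])
        edge = int(best[i_edge])
        if edge not in edge_to_clade:
            raise KeyError(f"edge {edge} missing from edge→clade table")
        for name in names:
            reads.append(
                PlacementRead(
                    read_id=str(name),
                    gene=gene,
                    clade=edge_to_clade[edge],
                    branch_length=float(best[i_pend]),
                    read_len=int((read_lengths or {}).get(name, default_read_len)),
                    sample_id=sample_id,
                    weight=float(best[i_lwr]),
                )
            )
    return reads
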