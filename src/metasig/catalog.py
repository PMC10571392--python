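"""Metagenome-assembled-genome (MAG) catalog rules.

A MAG catalog is built from per-sample genome bins by (1) scoring each bin
with the quality score QS = completeness - 5 x contamination, (2) tiering
bins against the MIMAG high/medium standard, (3) merging within-sample bins
that plausibly belong to one genome (near-equal depth and GC, identical
species label), (4) filtering to catalog-grade bins, and (5) dereplicating
the survivors at 95% nucleotide identity into species clusters whose
representative is the highest-QS member.  Species-level relative abundances
are rolled up to higher taxonomic ranks by summation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

RANKS = ("domain", "phylum", "class", "order", "family", "genus", "species")
_RANK_PREFIX = dict(zip(RANKS, ("d__", "p__", "c__", "o__", "f__", "g__", "s__")))


class ValidationError(ValueError):
    """Raised when an input violates a documented contract."""


@dataclass
class MAGRecord:
    """One genome bin with its quality, coverage, and taxonomy metadata.

    ``quality_score`` is always recomputed from completeness and
    contamination; a value stored in an input table is never trusted.
    """

    id: str
    sample_id: str
    completeness: float
    contamination: float
    depth: float = 0.0
    gc: float = 0.5
    taxonomy: tuple = ("", "", "", "", "", "", "")
    has_rrna_5s: bool = False
    has_rrna_16s: bool = False
    has_rrna_23s: bool = False
    n_trna: int = 0
    needs_reestimation: bool = False
    size: float = 1.0  # relative weight used for merged-bin averaging

    def __post_init__(self):
        if not 0 <= self.completeness <= 100:
            raise ValidationError(
                f"completeness must be in [0, 100], got {self.completeness}"
            )
        if self.contamination < 0:
            raise ValidationError(
                f"contamination must be >= 0, got {self.contamination}"
            )
        if self.depth < 0:
            raise ValidationError(f"depth must be >= 0, got {self.depth}")
        if not 0 <= self.gc <= 1:
            raise ValidationError(f"gc must be a fraction in [0, 1], got {self.gc}")
        if len(self.taxonomy) != 7:
            raise ValidationError("taxonomy must have 7 ranks (domain..species)")
        self.taxonomy = tuple(self.taxonomy)

    @property
    def quality_score(self) -> float:
        return quality_score(self.completeness, self.contamination)

    @property
    def species_label(self) -> str:
        return self.taxonomy[6]

    def rank(self, name: str) -> str:
        if name not in RANKS:
            raise ValidationError(f"unknown rank {name!r}; expected one of {RANKS}")
        return self.taxonomy[RANKS.index(name)]


@dataclass
class SpeciesCluster:
    """A dereplication cluster: member MAG ids and the representative."""

    members: list
    representative: str
    species_id: str = ""

    def __post_init__(self):
        if self.representative not in self.members:
            raise ValidationError("representative must be a cluster member")


def quality_score(completeness: float, contamination: float) -> float:
    """QS = completeness - 5 x contamination.

    Parameters are percentages: completeness in [0, 100], contamination >= 0.
    """
    if not 0 <= completeness <= 100:
        raise ValidationError(f"completeness out of [0, 100]: {completeness}")
    if contamination < 0:
        raise ValidationError(f"negative contamination: {contamination}")
    return completeness - 5.0 * contamination


def classify_quality(record: MAGRecord) -> str:
    """MIMAG tier: ``high``, ``medium`` or ``fail``.

    high:   completeness > 90, contamination < 5, all of the 5S/16S/23S rRNA
            genes present, and at least 18 tRNAs.
    medium: completeness >= 70 and contamination < 10.
    """
    if (
        record.completeness > 90
        and record.contamination < 5
        and record.has_rrna_5s
        and record.has_rrna_16s
        and record.has_rrna_23s
        and record.n_trna >= 18
    ):
        return "high"
    if record.completeness >= 70 and record.contamination < 10:
        return "medium"
    return "fail"


def filter_catalog(records) -> list:
    """Keep catalog-grade bins: completeness > 70, contamination < 5, QS > 60.

    All three inequalities are strict; QS is recomputed, never read from input.
    """
    return [
        r
        for r in records
        if r.completeness > 70 and r.contamination < 5 and r.quality_score > 60
    ]


def _mergeable(a: MAGRecord, b: MAGRecord, depth_tol: float, gc_tol: float,
               gc_relative: bool) -> bool:
    if not a.species_label or a.species_label != b.species_label:
        return False
    denom = 0.5 * (a.depth + b.depth)
    if denom == 0:
        depth_ok = a.depth == b.depth
    else:
        depth_ok = abs(a.depth - b.depth) / denom <= depth_tol
    if gc_relative:
        gdenom = 0.5 * (a.gc + b.gc)
        gc_ok = gdenom == 0 or abs(a.gc - b.gc) / gdenom <= gc_tol
    else:
        # absolute tolerance expressed in GC percentage points
        gc_ok = abs(a.gc - b.gc) * 100.0 <= gc_tol * 100.0
    return depth_ok and gc_ok


def merge_bins(records, depth_tol: float = 0.10, gc_tol: float = 0.02,
               gc_relative: bool = False) -> list:
    """Merge within-sample bins that look like fragments of one genome.

    Two bins are pairwise mergeable iff their relative depth difference
    ``|d1-d2| / mean(d1,d2)`` is <= ``depth_tol``, their GC difference is
    within ``gc_tol`` (absolute percentage points by default), and they share
    an identical, non-empty species label.  Merge groups are the connected
    components of the mergeability graph (single linkage), which makes the
    result independent of input order.  Merged depth and GC are size-weighted
    means; completeness/contamination of a merged record are flagged for
    re-estimation rather than recomputed.
    """
    records = list(records)
    if not records:
        return []
    samples = {r.sample_id for r in records}
    if len(samples) != 1:
        raise ValidationError(
            f"merge_bins operates within one sample, got {sorted(samples)}"
        )
    n = len(records)
    order = sorted(range(n), key=lambda i: records[i].id)
    # union-find over the mergeability graph
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for ii in range(n):
        for jj in range(ii + 1, n):
            i, j = order[ii], order[jj]
            if _mergeable(records[i], records[j], depth_tol, gc_tol, gc_relative):
                parent[find(i)] = find(j)

    groups: dict = {}
    for i in order:
        groups.setdefault(find(i), []).append(records[i])

    merged = []
    for group in groups.values():
        if len(group) == 1:
            merged.append(group[0])
            continue
        group = sorted(group, key=lambda r: r.id)
        w = np.array([r.size for r in group], dtype=float)
        w = w / w.sum()
        merged.append(
            replace(
                group[0],
                id="+".join(r.id for r in group),
                depth=float(np.dot(w, [r.depth for r in group])),
                gc=float(np.dot(w, [r.gc for r in group])),
                size=float(sum(r.size for r in group)),
                needs_reestimation=True,
            )
        )
    return sorted(merged, key=lambda r: r.id)


def dereplicate(records, identity: pd.DataFrame, threshold: float = 0.95) -> list:
    """Greedy leader clustering of genomes at a nucleotide-identity threshold.

    Records are visited in decreasing QS order (ties broken lexicographically
    by id).  Each record joins the first existing cluster whose representative
    it matches at identity strictly above ``threshold``; otherwise it founds a
    new cluster with itself as representative.  Because visiting order is by
    QS, every representative is the highest-QS member of its cluster.
    """
    records = list(records)
    ids = [r.id for r in records]
    missing = set(ids) - set(identity.index) | set(ids) - set(identity.columns)
    if missing:
        raise ValidationError(f"identity matrix missing entries for {sorted(missing)}")
    order = sorted(records, key=lambda r: (-r.quality_score, r.id))
    clusters: list[SpeciesCluster] = []
    for rec in order:
        for cl in clusters:
            if float(identity.loc[cl.representative, rec.id]) > threshold:
                cl.members.append(rec.id)
                break
        else:
            clusters.append(SpeciesCluster(members=[rec.id], representative=rec.id))
    for k, cl in enumerate(clusters):
        cl.species_id = f"sp{k + 1:04d}"
    return clusters


def rollup_taxa(table: pd.DataFrame, taxonomy: dict, rank: str) -> pd.DataFrame:
    """Sum feature relative abundances sharing a label at ``rank``.

    ``taxonomy`` maps feature id -> 7-tuple (domain..species).  Features with
    an empty label at the rank are pooled under ``"unclassified"``.  Per-sample
    totals are conserved exactly.
    """
    if rank not in RANKS:
        raise ValidationError(f"unknown rank {rank!r}; expected one of {RANKS}")
    if table.shape[1] == 0:
        return table.copy()
    idx = RANKS.index(rank)
    labels = []
    for feat in table.columns:
        if feat not in taxonomy:
            raise ValidationError(f"feature {feat!r} has no taxonomy entry")
        lab = taxonomy[feat][idx]
        labels.append(lab if lab else "unclassified")
    return table.T.groupby(pd.Index(labels, name=rank)).sum().T


def gc_content(sequences) -> float:
    """GC fraction of one or more DNA sequences, ambiguity codes excluded.

    Accepts a string, a Bio.SeqRecord, or an iterable of either; counts are
    pooled.  Only unambiguous A/C/G/T (case-insensitive) enter numerator and
    denominator.  Raises if no unambiguous base is present.
    """
    if isinstance(sequences, str) or hasattr(sequences, "seq"):
        sequences = [sequences]
    gc = at = 0
    for s in sequences:
        seq = str(s.seq if hasattr(s, "seq") else s).upper()
        gc += seq.count("G") + seq.count("C")
        at += seq.count("A") + seq.count("T")
    if gc + at == 0:
        raise ValidationError("no unambiguous A/C/G/T bases; GC undefined")
    return gc / (gc + at)


def kmer_identity(seq_a: str, seq_b: str, k: int = 8) -> float:
    """Toy k-mer containment identity for fixture construction only.

    Not an ANI algorithm: a symmetric containment index of k-mer sets used to
    build small self-consistent identity matrices in tests and simulations.
    """
    def kmers(s):
        s = s.upper()
        return {s[i:i + k] for i in range(len(s) - k + 1)}

    ka, kb = kmers(seq_a), kmers(seq_b)
    if not ka or not kb:
        raise ValidationError("sequence shorter than k")
    return len(ka & kb) / min(len(ka), len(kb))


# ---------------------------------------------------------------------------
# TSV interfaces


def taxonomy_to_string(tax) -> str:
    return ";".join(p + t for p, t in zip(_RANK_PREFIX.values(), tax))


def taxonomy_from_string(s: str) -> tuple:
    parts = s.split(";")
    out = []
    for prefix, part in zip(_RANK_PREFIX.values(), parts + [""] * (7 - len(parts))):
        part = part.strip()
        out.append(part[len(prefix):] if part.startswith(prefix) else part)
    return tuple(out)


def read_mags_tsv(path) -> list:
    df = pd.read_csv(path, sep="\t", dtype={"id": str, "sample_id": str})
    records = []
    for _, row in df.iterrows():
        records.append(
            MAGRecord(
                id=row["id"],
                sample_id=row["sample_id"],
                completeness=float(row["completeness"]),
                contamination=float(row["contamination"]),
                depth=float(row.get("depth", 0.0)),
                gc=float(row.get("gc", 0.5)),
                taxonomy=taxonomy_from_string(str(row.get("taxonomy", ""))),
                has_rrna_5s=bool(row.get("rrna_5s", False)),
                has_rrna_16s=bool(row.get("rrna_16s", False)),
                has_rrna_23s=bool(row.get("rrna_23s", False)),
                n_trna=int(row.get("n_trna", 0)),
            )
        )
    return records


def write_mags_tsv(records, path) -> None:
    rows = [
        {
            "id": r.id,
            "sample_id": r.sample_id,
            "completeness": r.completeness,
            "contamination": r.contamination,
            "depth": r.depth,
            "gc": r.gc,
            "taxonomy": taxonomy_to_string(r.taxonomy),
            "rrna_5s": r.has_rrna_5s,
            "rrna_16s": r.has_rrna_16s,
            "rrna_23s": r.has_rrna_23s,
            "n_trna": r.n_trna,
        }
        for r in records
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def clusters_to_frame(clusters) -> pd.DataFrame:
    rows = []
    for cl in clusters:
        for m in cl.members:
            rows.append(
                {
                    "species_id": cl.species_id,
                    "mag_id": m,
                    "is_representative": m == cl.representative,
                }
            )
    return pd.DataFrame(rows, columns=["species_id", "mag_id", "is_representative"])
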