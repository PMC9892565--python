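"""FACS-seq analysis of split-ribozyme insertion libraries.

A transposon-built library places a cut at (ideally) every position of the
ribozyme; each variant's amplicon spans the junction between the 5'
ribozyme fragment and the first RNA guide, so the split site of a read is
identified by locating that junction.  Sorting enriches variants with the
desired on/off behaviour; comparing per-site read frequencies between
sorted and unsorted libraries yields a relative enrichment per split site,
a two-tailed t-test across replicate libraries, and a flag for sites lost
during selection.

Reads are matched in the given orientation and as reverse complements;
junction matching uses an exact seed with a pigeonhole fallback for reads
carrying up to ``max_mismatches`` substitutions in the anchor.
"""

from __future__ import annotations

import gzip
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from scipy import stats

from .sequences import NucSeq, reverse_complement

__all__ = [
    "SplitJunctionIndex",
    "SplitSiteCountTable",
    "locate_split_junction",
    "count_split_sites",
    "relative_enrichment",
    "site_ttest",
    "flag_lost_sites",
    "classify_amplicons",
]


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


class SplitJunctionIndex:
    """Index of fragment/guide junction sequences for split-site calling.

    For split site ``s`` the junction string is the last ``min_anchor``
    bases of ``upstream + ribozyme[1..s]`` followed by the first
    ``min_anchor`` bases of guide1.  ``upstream`` is the amplicon context
    5' of the ribozyme (empty by default); without it, sites with
    ``s < min_anchor`` cannot be anchored and are excluded from the index.
    """

    def __init__(
        self,
        ribozyme: NucSeq | str,
        guide1: NucSeq | str,
        upstream: str = "",
        min_anchor: int = 12,
        max_mismatches: int = 1,
    ):
        rib = str(ribozyme)
        g1 = str(guide1)
        if len(g1) < min_anchor:
            raise ValueError(f"guide1 shorter than min_anchor={min_anchor}")
        self.ribozyme = rib
        self.min_anchor = int(min_anchor)
        self.max_mismatches = int(max_mismatches)
        self.n_sites = len(rib) - 1
        k = self.min_anchor
        right = g1[:k]
        self._exact: dict[str, int] = {}
        self._half_left: dict[str, list[int]] = {}
        self._half_right: dict[str, list[int]] = {}
        self._junction: dict[int, str] = {}
        ambiguous: set[str] = set()
        for s in range(1, self.n_sites + 1):
            prefix = upstream + rib[:s]
            if len(prefix) < k:
                continue
            j = prefix[-k:] + right
            self._junction[s] = j
            if j in self._exact:
                ambiguous.add(j)
            else:
                self._exact[j] = s
            self._half_left.setdefault(j[:k], []).append(s)
            self._half_right.setdefault(j[k:], []).append(s)
        for j in ambiguous:
            self._exact[j] = -1  # sentinel: non-unique junction
        self.indexed_sites = sorted(self._junction)

    @property
    def window(self) -> int:
        return 2 * self.min_anchor

    def _scan(self, read: str) -> set[int]:
        w = self.window
        hits: set[int] = set()
        for i in range(len(read) - w + 1):
            sub = read[i : i + w]
            s = self._exact.get(sub)
            if s is not None:
                if s == -1:
                    hits.update(
                        t for t in self._half_left.get(sub[: self.min_anchor], [])
                        if self._junction[t] == sub
                    )
                else:
                    hits.add(s)
        if hits or self.max_mismatches == 0:
            return hits
        # pigeonhole: a window with <= max_mismatches (=1) substitutions
        # matches at least one anchor half exactly
        k = self.min_anchor
        for i in range(len(read) - w + 1):
            sub = read[i : i + w]
            cands = set(self._half_left.get(sub[:k], ())) | set(
                self._half_right.get(sub[k:], ())
            )
            for s in cands:
                if _hamming(sub, self._junction[s]) <= self.max_mismatches:
                    hits.add(s)
        return hits

    def locate(self, read: str) -> tuple[int | None, str]:
        """Split site of a read, or ``(None, reason)``.

        Both orientations are searched; the call must be unique across all
        matching windows of both orientations (reason ``"ambiguous"``
        otherwise, ``"no_junction"`` if nothing matches).
        """
        read = read.upper().replace("T", "U")
        if len(read) < self.window:
            return None, "read_too_short"
        hits = self._scan(read) | self._scan(reverse_complement(read))
        if not hits:
            return None, "no_junction"
        if len(hits) > 1:
            return None, "ambiguous"
        return hits.pop(), "ok"


def locate_split_junction(
    read: str,
    ribozyme: NucSeq | str,
    guide1: NucSeq | str,
    min_anchor: int = 12,
    max_mismatches: int = 1,
    upstream: str = "",
) -> tuple[int | None, str]:
    """One-shot junction location (builds a throwaway index)."""
    idx = SplitJunctionIndex(ribozyme, guide1, upstream, min_anchor, max_mismatches)
    return idx.locate(read)


@dataclass
class SplitSiteCountTable:
    """Per split-site read counts and frequencies across libraries.

    ``counts`` is indexed by split site (1..L-1) with one column per
    library label; ``unassigned`` tallies reads per (library, reason).
    Frequencies are counts over the library's assigned total.
    """

    counts: pd.DataFrame
    unassigned: pd.DataFrame
    n_possible_sites: int
    metadata: dict = field(default_factory=dict)

    @property
    def totals(self) -> pd.Series:
        return self.counts.sum(axis=0)

    @property
    def frequencies(self) -> pd.DataFrame:
        tot = self.totals.replace(0, np.nan)
        return self.counts.div(tot, axis=1).fillna(0.0)

    @property
    def coverage(self) -> pd.Series:
        """Fraction of the L-1 possible sites observed per library."""
        return (self.counts > 0).sum(axis=0) / self.n_possible_sites

    def total_reads(self, label: str) -> int:
        extra = self.unassigned.loc[self.unassigned.library == label, "count"].sum()
        return int(self.counts[label].sum() + extra)


def _open_maybe_gzip(path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def _iter_fastq(path) -> Iterable[str]:
    with _open_maybe_gzip(path) as fh:
        for rec in SeqIO.parse(fh, "fastq"):
            yield str(rec.seq)


def count_split_sites(
    fastq_by_library: Mapping[str, str | Path | Sequence[str | Path]],
    ribozyme: NucSeq | str,
    guide1: NucSeq | str,
    upstream: str = "",
    min_anchor: int = 12,
    max_mismatches: int = 1,
    reads_by_library: Mapping[str, Iterable[str]] | None = None,
) -> SplitSiteCountTable:
    """Assign every read of every library to a split site and tabulate.

    ``fastq_by_library`` maps a library label (e.g. ``unsorted``,
    ``sorted_r1``) to one or more FASTQ paths (Phred+33, ``.gz``
    autodetected); ``reads_by_library`` may instead supply iterables of
    read strings directly.  Unassigned reads are tallied with reason codes.
    """
    index = SplitJunctionIndex(ribozyme, guide1, upstream, min_anchor, max_mismatches)
    sites = pd.RangeIndex(1, index.n_sites + 1, name="split_index")
    labels = list(fastq_by_library) if reads_by_library is None else list(reads_by_library)
    counts = pd.DataFrame(0, index=sites, columns=labels, dtype=int)
    un_rows = []
    for label in labels:
        if reads_by_library is not None:
            read_iter: Iterable[str] = reads_by_library[label]
        else:
            paths = fastq_by_library[label]
            if isinstance(paths, (str, Path)):
                paths = [paths]
            read_iter = (r for p in paths for r in _iter_fastq(p))
        reasons: dict[str, int] = {}
        col = counts[label].to_numpy()
        for read in read_iter:
            s, reason = index.locate(read)
            if s is None:
                reasons[reason] = reasons.get(reason, 0) + 1
            else:
                col[s - 1] += 1
        counts[label] = col
        for reason, n in sorted(reasons.items()):
            un_rows.append({"library": label, "reason": reason, "count": n})
    unassigned = pd.DataFrame(un_rows, columns=["library", "reason", "count"])
    meta = {
        "min_anchor": min_anchor,
        "max_mismatches": max_mismatches,
        "upstream_context_len": len(upstream),
        "indexed_sites": len(index.indexed_sites),
    }
    return SplitSiteCountTable(counts, unassigned, index.n_sites, meta)


def site_ttest(sorted_freqs, unsorted_freqs):
    """Homoscedastic two-sample two-tailed t-test on per-site frequencies.

    Accepts 1-d arrays (one site) or 2-d arrays of shape
    ``(n_sites, n_replicates)``; requires >= 2 replicates per group.
    Identical groups with zero pooled variance give p = 1 (no evidence of
    a difference); zero variance with differing means gives p = 0.
    """
    a = np.atleast_2d(np.asarray(sorted_freqs, dtype=float))
    b = np.atleast_2d(np.asarray(unsorted_freqs, dtype=float))
    if a.shape[-1] < 2 or b.shape[-1] < 2:
        raise ValueError("need >= 2 replicates per group for a t-test")
    with warnings.catch_warnings():
        # near-identical groups trigger a scipy precision warning; that
        # case is handled explicitly below
        warnings.simplefilter("ignore", RuntimeWarning)
        res = stats.ttest_ind(a, b, axis=-1, equal_var=True)
    p = np.asarray(res.pvalue, dtype=float)
    degenerate = (a.var(axis=-1) == 0) & (b.var(axis=-1) == 0)
    same_mean = a.mean(axis=-1) == b.mean(axis=-1)
    p = np.where(degenerate, np.where(same_mean, 1.0, 0.0), p)
    return float(p[0]) if p.shape == (1,) and np.ndim(sorted_freqs) == 1 else p


def relative_enrichment(
    table: SplitSiteCountTable,
    sorted_labels: Sequence[str],
    unsorted_labels: Sequence[str],
    pseudocount: float = 0.5,
    lost_threshold: float | None = None,
) -> pd.DataFrame:
    """Relative enrichment of each split site: sorted vs unsorted frequency.

    Frequencies are computed per library, averaged across replicate
    libraries, and the enrichment is their ratio with a pseudocount
    ``pseudocount / mean(library total)`` added to numerator and
    denominator.  With >= 2 replicates per group a per-site homoscedastic
    two-tailed t-test on the library frequencies is included.  Lost sites
    (sorted frequency at/below threshold; default: zero sorted reads) are
    flagged via :func:`flag_lost_sites`.
    """
    missing = [l for l in (*sorted_labels, *unsorted_labels) if l not in table.counts]
    if missing:
        raise KeyError(f"libraries not in table: {missing}")
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    freqs = table.frequencies
    f_sorted = freqs[list(sorted_labels)]
    f_unsorted = freqs[list(unsorted_labels)]
    mean_s = f_sorted.mean(axis=1)
    mean_u = f_unsorted.mean(axis=1)
    pt_s = pseudocount / max(table.totals[list(sorted_labels)].mean(), 1.0)
    pt_u = pseudocount / max(table.totals[list(unsorted_labels)].mean(), 1.0)
    if pseudocount == 0 and (mean_u == 0).any():
        raise ZeroDivisionError(
            "sites absent from the unsorted libraries with pseudocount 0"
        )
    enrichment = (mean_s + pt_s) / (mean_u + pt_u)
    out = pd.DataFrame(
        {
            "freq_sorted": mean_s,
            "freq_unsorted": mean_u,
            "enrichment": enrichment,
            "log2_enrichment": np.log2(enrichment),
        }
    )
    if len(sorted_labels) >= 2 and len(unsorted_labels) >= 2:
        out["p_value"] = site_ttest(f_sorted.to_numpy(), f_unsorted.to_numpy())
    else:
        out["p_value"] = np.nan
    return flag_lost_sites(out, threshold=lost_threshold)


def flag_lost_sites(results: pd.DataFrame, threshold: float | None = None) -> pd.DataFrame:
    """Flag sites lost during selection.

    Default rule: a site is lost when it received zero sorted reads
    (sorted frequency == 0).  A positive ``threshold`` instead flags sites
    with mean sorted frequency strictly below it.  The rule is recorded in
    ``results.attrs``.
    """
    out = results.copy()
    if threshold is None:
        out["lost"] = out["freq_sorted"] <= 0
        out.attrs["lost_threshold"] = "zero sorted reads"
    else:
        out["lost"] = out["freq_sorted"] < threshold
        out.attrs["lost_threshold"] = float(threshold)
    return out


def classify_amplicons(
    reads: Iterable[str],
    spliced_junction: NucSeq | str,
    unspliced_5: NucSeq | str,
    unspliced_3: NucSeq | str,
    k: int = 12,
) -> dict[str, float]:
    """Fractions of spliced / unspliced / other amplicon reads.

    Each junction argument is sequence context centred on the junction of
    interest (exon1-end+exon2-start for the spliced product; exon/intron
    boundaries for the unspliced pre-mRNA); the probe is the central
    ``2k``-mer.  Reads are assigned by exact probe match (either
    orientation) with precedence spliced -> unspliced -> other; the
    returned fractions sum to 1 (all zero for no reads).
    """

    def probe(ctx: NucSeq | str) -> str:
        s = str(ctx)
        mid = len(s) // 2
        if mid < k or len(s) - mid < k:
            raise ValueError(f"junction context shorter than 2k={2 * k}")
        return s[mid - k : mid + k]

    probes = [
        ("spliced", probe(spliced_junction)),
        ("unspliced", probe(unspliced_5)),
        ("unspliced", probe(unspliced_3)),
    ]
    tallies = {"spliced": 0, "unspliced": 0, "other": 0}
    n = 0
    for read in reads:
        read = read.upper().replace("T", "U")
        if len(read) < 2 * k:
            raise ValueError(f"read shorter than probe length 2k={2 * k}")
        rc = reverse_complement(read)
        n += 1
        for cls, p in probes:
            if p in read or p in rc:
                tallies[cls] += 1
                break
        else:
            tallies["other"] += 1
    if n == 0:
        return {cls: 0.0 for cls in tallies}
    return {cls: c / n for cls, c in tallies.items()}
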