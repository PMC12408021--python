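"""MinHash genome sketching and Mash distances.

A bottom-s sketch keeps the s smallest 64-bit hash values over the
canonical k-mers of a genome (canonical = lexicographic minimum of the
2-bit encoding of a k-mer and its reverse complement). The Mash distance
between two sketches estimates k-mer Jaccard similarity j from the s
smallest hashes of the sketch union and maps it to a mutation-rate-like
distance d = -ln(2j/(1+j))/k.

The hash is a fixed 64-bit mixing function (the splitmix64 finalizer) so
sketches are deterministic across runs and platforms. Bit compatibility
with external sketching tools is not promised — only metric equivalence.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view
from scipy.stats import mannwhitneyu

_BASE = {"A": 0, "C": 1, "G": 2, "T": 3}
_MASK64 = np.uint64(0xFFFFFFFFFFFFFFFF)


@dataclass
class Sketch:
    """Bottom-s MinHash signature of one genome."""

    genome_id: str
    k: int
    s: int
    hashes: np.ndarray  # sorted, strictly increasing uint64

    def __post_init__(self):
        if self.k < 1:
            raise ValueError("k must be >= 1")
        self.hashes = np.asarray(self.hashes, dtype=np.uint64)
        if len(self.hashes) > self.s:
            raise ValueError("more hashes than sketch size")
        if len(self.hashes) > 1 and not (self.hashes[1:] > self.hashes[:-1]).all():
            raise ValueError("hashes must be strictly increasing")

    def to_dict(self) -> dict:
        return {"genome_id": self.genome_id, "k": self.k, "s": self.s,
                "hashes": [int(h) for h in self.hashes]}

    @classmethod
    def from_dict(cls, d: dict) -> "Sketch":
        return cls(d["genome_id"], d["k"], d["s"],
                   np.array(d["hashes"], dtype=np.uint64))


def _splitmix64(x: np.ndarray) -> np.ndarray:
    """Fixed 64-bit mixing function (splitmix64 finalizer)."""
    x = x.astype(np.uint64)
    x = (x + np.uint64(0x9E3779B97F4A7C15)) & _MASK64
    x = ((x ^ (x >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)) & _MASK64
    x = ((x ^ (x >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)) & _MASK64
    return x ^ (x >> np.uint64(31))


def _canonical_kmer_codes(seq: str, k: int) -> np.ndarray:
    """2-bit codes of canonical k-mers; windows with ambiguous bases skipped."""
    codes = np.fromiter((_BASE.get(c, 4) for c in seq.upper()), dtype=np.int64,
                        count=len(seq))
    if len(codes) < k:
        return np.empty(0, dtype=np.uint64)
    valid = codes < 4
    win = sliding_window_view(codes, k)
    ok = sliding_window_view(valid, k).all(axis=1)
    win = win[ok].astype(np.uint64)
    if win.size == 0:
        return np.empty(0, dtype=np.uint64)
    powers = (np.uint64(4) ** np.arange(k - 1, -1, -1, dtype=np.uint64))
    fwd = (win * powers).sum(axis=1, dtype=np.uint64)
    rc = ((np.uint64(3) - win)[:, ::-1] * powers).sum(axis=1, dtype=np.uint64)
    return np.minimum(fwd, rc)


def sketch(sequences, genome_id: str = "", k: int = 21, s: int = 1000) -> Sketch:
    """Sketch a genome given as one sequence string or an iterable of
    (id, sequence) records / plain strings."""
    if k > 31:
        raise ValueError("k must be <= 31 for 2-bit encoding in 64 bits")
    if isinstance(sequences, str):
        sequences = [sequences]
    all_hashes = []
    total_len = 0
    for rec in sequences:
        seq = rec[1] if isinstance(rec, tuple) else str(getattr(rec, "seq", rec))
        total_len += len(seq)
        kmers = _canonical_kmer_codes(seq, k)
        if kmers.size:
            all_hashes.append(_splitmix64(kmers))
    if total_len < k:
        raise ValueError(f"total sequence length {total_len} < k={k}")
    if not all_hashes:
        raise ValueError("no valid k-mers (ambiguous bases?)")
    h = np.unique(np.concatenate(all_hashes))
    return Sketch(genome_id, k, s, h[:s])


def mash_distance(a: Sketch, b: Sketch) -> float:
    """Mash distance d = -ln(2j/(1+j))/k with j estimated from the s
    smallest hashes of the sketch union; j=0 saturates to d=1."""
    if a.k != b.k:
        raise ValueError(f"mismatched k: {a.k} vs {b.k}")
    s = min(a.s, b.s)
    union = np.union1d(a.hashes, b.hashes)[:s]
    shared = np.intersect1d(a.hashes, b.hashes, assume_unique=True)
    n_union = len(union)
    if n_union == 0:
        raise ValueError("empty sketches")
    n_shared = np.isin(union, shared, assume_unique=True).sum()
    j = n_shared / n_union
    if j == 0:
        return 1.0
    return float(max(0.0, -np.log(2.0 * j / (1.0 + j)) / a.k))


def sketch_jaccard(a: Sketch, b: Sketch) -> float:
    """MinHash estimate of the k-mer Jaccard index."""
    s = min(a.s, b.s)
    union = np.union1d(a.hashes, b.hashes)[:s]
    shared = np.intersect1d(a.hashes, b.hashes, assume_unique=True)
    return float(np.isin(union, shared, assume_unique=True).sum() / len(union))


def pairwise_mash(sketches: dict[str, Sketch]) -> pd.DataFrame:
    ids = sorted(sketches)
    n = len(ids)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = mash_distance(sketches[ids[i]], sketches[ids[j]])
    return pd.DataFrame(d, index=ids, columns=ids)


def save_sketches(sketches, path):
    with open(path, "w") as fh:
        json.dump({"format": "gutstrain-sketch-v1",
                   "sketches": [s.to_dict() for s in sketches]}, fh)


def load_sketches(path) -> dict[str, Sketch]:
    with open(path) as fh:
        payload = json.load(fh)
    out = {}
    for d in payload["sketches"]:
        sk = Sketch.from_dict(d)
        out[sk.genome_id] = sk
    return out


# ------------------------------------------------ stratified comparison

@dataclass
class StratifiedDistanceReport:
    species: str
    related_case: list = field(default_factory=list)
    related_control: list = field(default_factory=list)
    unrelated: list = field(default_factory=list)
    u_related_vs_unrelated: float = np.nan
    p_related_vs_unrelated: float = np.nan
    u_case_vs_control: float = np.nan
    p_case_vs_control: float = np.nan

    @property
    def related(self) -> list:
        return self.related_case + self.related_control

    def to_row(self) -> dict:
        return {"species": self.species,
                "n_related": len(self.related), "n_unrelated": len(self.unrelated),
                "median_related": float(np.median(self.related)) if self.related else np.nan,
                "median_unrelated": float(np.median(self.unrelated)) if self.unrelated else np.nan,
                "p_related_vs_unrelated": self.p_related_vs_unrelated,
                "n_related_case": len(self.related_case),
                "n_related_control": len(self.related_control),
                "p_case_vs_control": self.p_case_vs_control}


def stratified_comparison(distances: pd.DataFrame, genome_map: pd.DataFrame,
                          species: str) -> StratifiedDistanceReport:
    """Related (same-infant) vs unrelated (different-infant) genome-pair
    distances, and within related pairs case vs control, by two-sided
    Mann-Whitney U. ``genome_map`` needs columns genome_id, infant_id, group.

    Tests with an empty stratum are reported as not-applicable (NaN).
    """
    gm = genome_map.set_index("genome_id")
    ids = [g for g in distances.index if g in gm.index]
    if len(ids) < 2:
        raise ValueError(f"species {species}: need >= 2 mapped genomes")
    rep = StratifiedDistanceReport(species=species)
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            d = float(distances.loc[a, b])
            if gm.loc[a, "infant_id"] == gm.loc[b, "infant_id"]:
                if gm.loc[a, "group"] == "case":
                    rep.related_case.append(d)
                else:
                    rep.related_control.append(d)
            else:
                rep.unrelated.append(d)
    if rep.related and rep.unrelated:
        u, p = mannwhitneyu(rep.related, rep.unrelated, alternative="two-sided")
        rep.u_related_vs_unrelated, rep.p_related_vs_unrelated = float(u), float(p)
    if rep.related_case and rep.related_control:
        if rep.related_case == rep.related_control:
            rep.u_case_vs_control, rep.p_case_vs_control = np.nan, 1.0
        else:
            u, p = mannwhitneyu(rep.related_case, rep.related_control,
                                alternative="two-sided")
            rep.u_case_vs_control, rep.p_case_vs_control = float(u), float(p)
    return rep


def compare_top_species(sketches_by_species: dict[str, dict[str, Sketch]],
                        genome_map: pd.DataFrame,
                        top_n_species: int = 20) -> pd.DataFrame:
    """Run the stratified comparison across the species with most genomes
    (ties broken lexicographically)."""
    ranked = sorted(sketches_by_species,
                    key=lambda sp: (-len(sketches_by_species[sp]), sp))
    rows = []
    for sp in ranked[:top_n_species]:
        dm = pairwise_mash(sketches_by_species[sp])
        rows.append(stratified_comparison(dm, genome_map, sp).to_row())
    return pd.DataFrame(rows)
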