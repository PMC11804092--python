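"""Truth-annotated synthetic cohort generator.

Emulates the data shape of an indicine-cattle pangenome study at desk scale:
a multi-chromosome reference with interspersed LINE/SINE/LTR/DNA repeats,
implanted insertions (50 bp – 50 kb, size mixture skewed small, TE-dominated
composition), diploid presence/absence genotypes across five breeds, two
pseudohaplotype sequences per individual, and paired short reads with a
substitution-only error model.

Every generator is a pure function of (parameters, seed); the returned truth
objects let each downstream stage be scored exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_formats import GenomeSequence, Interval
from .kmer_align import decode_seq, encode_seq, revcomp

TE_CLASSES = ("LINE", "SINE", "LTR", "DNA")
CLASS_LENGTH_RANGE = {
    "LINE": (2000, 6000),
    "SINE": (150, 350),
    "LTR": (300, 1500),
    "DNA": (200, 1200),
}
# class weights for insertion composition: LINE-dominated, as in cattle
_TE_WEIGHTS = {"LINE": 0.55, "SINE": 0.20, "LTR": 0.15, "DNA": 0.10}

DEFAULT_BREEDS = ("Gir", "Kankrej", "Tharparkar", "Sahiwal", "RedSindhi")

#: log-uniform size mixture over [50, 50000), skewed small
DEFAULT_SIZE_MIX = (((50, 500), 0.60), ((500, 5000), 0.30), ((5000, 50000), 0.10))


@dataclass(frozen=True)
class RepeatConsensus:
    name: str
    te_class: str
    seq: str

    def __post_init__(self):
        lo, hi = CLASS_LENGTH_RANGE[self.te_class]
        if not lo <= len(self.seq) <= hi:
            raise ValueError(f"{self.name}: length {len(self.seq)} outside "
                             f"{self.te_class} range [{lo},{hi}]")


@dataclass
class TrueInsertion:
    id: str
    ref_breakpoint: Interval          # zero-width: start == end
    seq: str
    composition: dict                 # class -> base fraction (incl. "unique")
    allele_freq: float = 1.0

    def __post_init__(self):
        if self.ref_breakpoint.start != self.ref_breakpoint.end:
            raise ValueError("breakpoint must be zero-width")
        if len(self.seq) < 50:
            raise ValueError("insertion shorter than 50 bp")


@dataclass
class CohortTruth:
    samples: list                     # (sample_id, breed)
    genotypes: np.ndarray             # samples x insertions, {0,1,2}
    hap_choice: np.ndarray            # which haplotype carries a genotype-1 allele
    freqs: np.ndarray                 # insertions x breeds target frequencies
    breeds: tuple = DEFAULT_BREEDS


def _rand_seq(rng: np.random.Generator, n: int) -> np.ndarray:
    return rng.integers(0, 4, size=n, dtype=np.uint8)


def _mutate(arr: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Substitution-only divergence: each position flips to a different base
    with probability `rate`."""
    out = arr.copy()
    hit = np.nonzero(rng.random(len(arr)) < rate)[0]
    if len(hit):
        out[hit] = (out[hit] + rng.integers(1, 4, size=len(hit))) % 4
    return out


# ---------------------------------------------------------------------------
# Repeat library and reference
# ---------------------------------------------------------------------------

def make_repeat_library(n_per_class: int = 1, seed: int = 0) -> list[RepeatConsensus]:
    """Random consensus per TE class; i.i.d. sequences keep pairwise identity
    far below 80%."""
    if n_per_class < 1:
        raise ValueError("n_per_class must be ≥ 1")
    rng = np.random.default_rng(seed)
    lib = []
    for cls in TE_CLASSES:
        lo, hi = CLASS_LENGTH_RANGE[cls]
        for i in range(n_per_class):
            n = int(rng.integers(lo, hi + 1))
            lib.append(RepeatConsensus(f"{cls}-{i+1}", cls, decode_seq(_rand_seq(rng, n))))
    return lib


def make_reference(n_chrom: int, chrom_len: int, repeat_library: list[RepeatConsensus],
                   repeat_density: float = 0.3, seed: int = 0,
                   divergence_range: tuple = (0.05, 0.15),
                   ) -> tuple[list[GenomeSequence], list[tuple]]:
    """Reference backbone: uniform-random chromosomes with non-overlapping
    mutated repeat copies planted at `repeat_density` of the bases.

    Returns (chromosomes, truth) where truth rows are
    (Interval(chrom, start, end, strand), te_class, consensus_name).
    """
    if not 0.0 <= repeat_density <= 0.7:
        raise ValueError("repeat_density must lie in [0, 0.7]")
    rng = np.random.default_rng(seed)
    chroms: list[GenomeSequence] = []
    truth: list[tuple] = []
    for ci in range(n_chrom):
        name = f"chr{ci+1}"
        arr = _rand_seq(rng, chrom_len)
        target_bp = int(repeat_density * chrom_len)
        placed_bp = 0
        occupied: list[tuple[int, int]] = []
        attempts = 0
        while placed_bp < target_bp:
            attempts += 1
            if attempts > 50 * max(1, len(repeat_library)) * (target_bp // 100 + 10):
                raise ValueError("repeat density too high to place copies")
            cons = repeat_library[int(rng.integers(len(repeat_library)))]
            carr = encode_seq(cons.seq)
            # fragmental copies: 40-100% of the consensus, as in real genomes
            frac = rng.uniform(0.4, 1.0)
            clen = max(50, int(frac * len(carr)))
            coff = int(rng.integers(0, len(carr) - clen + 1))
            copy = carr[coff:coff + clen]
            pos = int(rng.integers(0, chrom_len - clen))
            if any(pos < e and s < pos + clen for s, e in occupied):
                continue
            div = rng.uniform(*divergence_range)
            copy = _mutate(copy, div, rng)
            strand = "+" if rng.random() < 0.5 else "-"
            if strand == "-":
                copy = encode_seq(revcomp(decode_seq(copy)))
            arr[pos:pos + clen] = copy
            occupied.append((pos, pos + clen))
            truth.append((Interval(name, pos, pos + clen, strand), cons.te_class, cons.name))
            placed_bp += clen
        chroms.append(GenomeSequence(name, decode_seq(arr)))
    truth.sort(key=lambda t: (t[0].chrom, t[0].start))
    return chroms, truth


# ---------------------------------------------------------------------------
# Insertions
# ---------------------------------------------------------------------------

def mixture_median(size_mix=DEFAULT_SIZE_MIX) -> float:
    """Closed-form median of the log-uniform size mixture."""
    acc = 0.0
    for (lo, hi), w in size_mix:
        if acc + w >= 0.5:
            q = (0.5 - acc) / w
            return float(lo * (hi / lo) ** q)
        acc += w
    return float(size_mix[-1][0][1])


def _draw_sizes(rng, n, size_mix):
    bins = np.array([w for _, w in size_mix])
    bins = bins / bins.sum()
    which = rng.choice(len(size_mix), size=n, p=bins)
    out = np.empty(n, np.int64)
    for i, b in enumerate(which):
        lo, hi = size_mix[b][0]
        out[i] = int(np.exp(rng.uniform(np.log(lo), np.log(hi))))
    return np.maximum(out, 50)


def _compose_insertion(rng, length, repeat_library, te_fraction,
                       te_divergence=(0.08, 0.15)):
    """Insertion sequence: unique filler with, usually, an embedded mutated
    TE fragment.  Returns (array, composition dict)."""
    arr = _rand_seq(rng, length)
    comp = dict.fromkeys(TE_CLASSES, 0.0)
    # probability of carrying TEs chosen so expected TE base share ≈ te_fraction
    p_te = min(1.0, te_fraction / 0.78)
    te_bp = 0
    if repeat_library and rng.random() < p_te and length >= 80:
        classes = list(TE_CLASSES)
        w = np.array([_TE_WEIGHTS[c] for c in classes])
        # fill up to a drawn share of the insertion with TE fragments,
        # possibly several, separated by short unique linkers; always keep
        # ≥70 unique bases so every planted insertion is callable under the
        # ≥50-unique-base retention rule
        target = min(int(length * rng.uniform(0.6, 0.95)), length - 70)
        cursor = int(rng.integers(0, max(1, length - target + 1)))
        while te_bp < target - 40 and cursor < length - 40:
            cls = classes[int(rng.choice(len(classes), p=w / w.sum()))]
            members = [r for r in repeat_library if r.te_class == cls]
            cons = members[int(rng.integers(len(members)))]
            carr = encode_seq(cons.seq)
            clen = min(target - te_bp, length - cursor, len(carr))
            if clen < 40:
                break
            coff = int(rng.integers(0, len(carr) - clen + 1))
            copy = _mutate(carr[coff:coff + clen], rng.uniform(*te_divergence), rng)
            if rng.random() < 0.5:
                copy = encode_seq(revcomp(decode_seq(copy)))
            arr[cursor:cursor + clen] = copy
            comp[cls] += clen / length
            te_bp += clen
            cursor += clen + int(rng.integers(10, 60))    # unique linker
    comp["unique"] = (length - te_bp) / length
    return arr, comp


def make_insertions(reference: list[GenomeSequence], repeat_library, n: int,
                    size_mix=DEFAULT_SIZE_MIX, seed: int = 0,
                    te_fraction: float = 0.60, min_spacing: int = 1000,
                    clean_margin: int = 100, repeat_truth=None,
                    clean_fraction: float = 1.0) -> list[TrueInsertion]:
    """Plant `n` insertions with left-aligned breakpoints ≥ `min_spacing`
    apart.  A `clean_fraction` of breakpoints stays ≥ `clean_margin` bp away
    from planted repeat intervals (needs `repeat_truth`)."""
    rng = np.random.default_rng(seed)
    if n == 0:
        return []
    sizes = _draw_sizes(rng, n, size_mix)
    ref_arrs = {s.name: encode_seq(s.seq) for s in reference}
    names = [s.name for s in reference]
    lengths = np.array([s.length for s in reference], dtype=float)
    repeat_iv = {}
    if repeat_truth:
        for iv, _cls, _nm in repeat_truth:
            repeat_iv.setdefault(iv.chrom, []).append((iv.start, iv.end))
    taken: dict[str, list[int]] = {nm: [] for nm in names}
    out: list[TrueInsertion] = []
    for i in range(n):
        need_clean = (i / max(n, 1)) < clean_fraction
        placed = False
        for _ in range(4000):
            ci = int(rng.choice(len(names), p=lengths / lengths.sum()))
            chrom = names[ci]
            bp = int(rng.integers(min_spacing, int(lengths[ci]) - min_spacing))
            if any(abs(bp - t) < min_spacing for t in taken[chrom]):
                continue
            if need_clean and any(s - clean_margin <= bp < e + clean_margin
                                  for s, e in repeat_iv.get(chrom, [])):
                continue
            placed = True
            break
        if not placed:
            raise ValueError("cannot place insertion breakpoints at the "
                             "requested spacing")
        arr, comp = _compose_insertion(rng, int(sizes[i]), repeat_library, te_fraction)
        ref = ref_arrs[chrom]
        # left-align (VCF convention) so the truth coordinate is canonical
        while bp > 0 and arr[-1] == ref[bp - 1]:
            arr = np.concatenate([arr[-1:], arr[:-1]])
            bp -= 1
        if any(abs(bp - t) < min_spacing for t in taken[chrom]):
            continue
        taken[chrom].append(bp)
        out.append(TrueInsertion(f"INS_{len(out)+1:04d}",
                                 Interval(chrom, bp, bp), decode_seq(arr), comp))
    out.sort(key=lambda t: (t.ref_breakpoint.chrom, t.ref_breakpoint.start))
    for j, t in enumerate(out):
        t.id = f"INS_{j+1:04d}"
    return out


# ---------------------------------------------------------------------------
# Cohort genotypes
# ---------------------------------------------------------------------------

def default_freq_model(rng: np.random.Generator, n_insertions: int,
                       breeds=DEFAULT_BREEDS) -> np.ndarray:
    """Beta(0.3, 0.3) population frequency truncated to [0.01, 0.99], shared
    across breeds."""
    f = rng.beta(0.3, 0.3, size=n_insertions)
    f = np.clip(f, 0.01, 0.99)
    return np.tile(f[:, None], (1, len(breeds)))


def structured_freq_model(offset: float = 0.4):
    """Breed-structured frequencies: each insertion is assigned a 'home'
    breed whose frequency is raised by `offset` over a low base frequency."""
    def model(rng: np.random.Generator, n_insertions: int,
              breeds=DEFAULT_BREEDS) -> np.ndarray:
        base = np.clip(rng.beta(0.5, 3.0, size=n_insertions), 0.01, 0.99 - offset)
        f = np.tile(base[:, None], (1, len(breeds)))
        home = rng.integers(0, len(breeds), size=n_insertions)
        f[np.arange(n_insertions), home] += offset
        return np.clip(f, 0.01, 0.99)
    return model


def make_cohort(insertions: list[TrueInsertion], breeds=DEFAULT_BREEDS,
                n_per_breed=(20, 19, 20, 20, 19), freq_model=None,
                seed: int = 0) -> CohortTruth:
    """Diploid genotypes drawn binomially per sample from per-breed allele
    frequencies; the carrier haplotype of each heterozygote is recorded."""
    rng = np.random.default_rng(seed)
    if np.isscalar(n_per_breed):
        n_per_breed = (int(n_per_breed),) * len(breeds)
    if freq_model is None:
        freq_model = default_freq_model
    n_ins = len(insertions)
    freqs = freq_model(rng, n_ins, breeds)
    samples = []
    rows = []
    for bi, breed in enumerate(breeds):
        for si in range(n_per_breed[bi]):
            samples.append((f"{breed}_{si+1:02d}", breed))
            rows.append(rng.binomial(2, freqs[:, bi]) if n_ins else np.zeros(0, int))
    genotypes = np.array(rows, dtype=np.int8).reshape(len(samples), n_ins)
    hap_choice = rng.integers(0, 2, size=genotypes.shape).astype(np.int8)
    for j, ins in enumerate(insertions):
        ins.allele_freq = float(freqs[j].mean())
    return CohortTruth(samples, genotypes, hap_choice, freqs, tuple(breeds))


# ---------------------------------------------------------------------------
# Pseudohaplotypes
# ---------------------------------------------------------------------------

def splice_haplotype(reference: list[GenomeSequence], insertions, carry_mask,
                     suffix: str = "") -> list[GenomeSequence]:
    """Reference with the masked subset of insertions spliced in."""
    by_chrom: dict[str, list[TrueInsertion]] = {}
    for j, ins in enumerate(insertions):
        if carry_mask[j]:
            by_chrom.setdefault(ins.ref_breakpoint.chrom, []).append(ins)
    out = []
    for chrom in reference:
        todo = sorted(by_chrom.get(chrom.name, []), key=lambda t: t.ref_breakpoint.start)
        parts = []
        prev = 0
        for ins in todo:
            bp = ins.ref_breakpoint.start
            parts.append(chrom.seq[prev:bp])
            parts.append(ins.seq)
            prev = bp
        parts.append(chrom.seq[prev:])
        out.append(GenomeSequence(chrom.name + suffix, "".join(parts)))
    return out


def build_pseudohaplotypes(reference: list[GenomeSequence],
                           insertions: list[TrueInsertion],
                           genotypes: np.ndarray, hap_choice: np.ndarray,
                           ) -> tuple[list[GenomeSequence], list[GenomeSequence]]:
    """Two haplotype sequence sets for one sample.  Genotype 2 puts the
    insertion on both haplotypes, 1 on the recorded carrier haplotype."""
    mask1 = (genotypes == 2) | ((genotypes == 1) & (hap_choice == 0))
    mask2 = (genotypes == 2) | ((genotypes == 1) & (hap_choice == 1))
    return (splice_haplotype(reference, insertions, mask1),
            splice_haplotype(reference, insertions, mask2))


def fragment_contigs(seqs: list[GenomeSequence], n50_target: int,
                     seed: int = 0) -> list[GenomeSequence]:
    """Optionally emulate assembly contiguity: cut sequences into contigs of
    roughly the target length (±15%), whose N50 therefore lands near
    `n50_target` even for short genomes."""
    rng = np.random.default_rng(seed)
    out = []
    for s in seqs:
        pos = 0
        i = 1
        while pos < s.length:
            ln = max(1000, int(rng.normal(n50_target, 0.15 * n50_target)))
            out.append(GenomeSequence(f"{s.name}_ctg{i}", s.seq[pos:pos + ln]))
            pos += ln
            i += 1
    return out


def contig_n50(seqs: list[GenomeSequence]) -> int:
    lens = sorted((s.length for s in seqs), reverse=True)
    half = sum(lens) / 2
    acc = 0
    for ln in lens:
        acc += ln
        if acc >= half:
            return ln
    return 0


# ---------------------------------------------------------------------------
# Reads
# ---------------------------------------------------------------------------

@dataclass
class ReadSet:
    """Paired reads as equal-length uint8 code matrices plus truth."""
    r1: np.ndarray
    r2: np.ndarray
    source_seq: np.ndarray       # index into the diploid sequence list
    source_pos: np.ndarray       # fragment start on that sequence
    frag_len: np.ndarray

    @property
    def n_pairs(self) -> int:
        return len(self.r1)


def simulate_reads(diploid: list[GenomeSequence], coverage: float = 30.0,
                   read_len: int = 100, frag_mean: int = 350, frag_sd: int = 50,
                   err_rate: float = 0.001, seed: int = 0) -> ReadSet:
    """Uniform paired fragments over the diploid sequences at the requested
    haploid depth, substitution errors at `err_rate` per base.

    `coverage` is the total depth over a haploid position when both
    haplotypes are present (each haplotype is sampled at coverage/2).
    """
    if coverage <= 0:
        raise ValueError("coverage must be positive")
    if frag_mean <= 2 * read_len:
        raise ValueError("frag_mean must exceed 2×read_len")
    rng = np.random.default_rng(seed)
    lens = np.array([s.length for s in diploid], dtype=np.int64)
    haploid = lens.sum() / 2.0
    n_pairs = int(round(coverage * haploid / (2 * read_len)))
    src = rng.choice(len(diploid), size=n_pairs, p=lens / lens.sum())
    fl = np.clip(np.round(rng.normal(frag_mean, frag_sd, n_pairs)).astype(np.int64),
                 2 * read_len, None)
    fl = np.minimum(fl, lens[src])
    pos = (rng.random(n_pairs) * (lens[src] - fl + 1)).astype(np.int64)
    arrs = [encode_seq(s.seq) for s in diploid]
    r1 = np.empty((n_pairs, read_len), np.uint8)
    r2 = np.empty((n_pairs, read_len), np.uint8)
    for i in range(n_pairs):
        a = arrs[src[i]]
        p, f = pos[i], fl[i]
        r1[i] = a[p:p + read_len]
        r2[i] = a[p + f - read_len:p + f][::-1]
    r2 = np.where(r2 == 4, np.uint8(4), (3 - r2).astype(np.uint8))
    if err_rate > 0:
        for mat in (r1, r2):
            hit = rng.random(mat.shape) < err_rate
            n_err = int(hit.sum())
            if n_err:
                mat[hit] = (mat[hit] + rng.integers(1, 4, size=n_err).astype(np.uint8)) % 4
    return ReadSet(r1, r2, src, pos, fl)


def write_fastq_pair(reads: ReadSet, path1, path2, prefix: str = "read") -> None:
    qual = "I" * reads.r1.shape[1]
    with open(path1, "w") as f1, open(path2, "w") as f2:
        for i in range(reads.n_pairs):
            f1.write(f"@{prefix}_{i}/1\n{decode_seq(reads.r1[i])}\n+\n{qual}\n")
            f2.write(f"@{prefix}_{i}/2\n{decode_seq(reads.r2[i])}\n+\n{qual}\n")
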