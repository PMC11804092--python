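"""Cohort genotyping and population structure.

Short reads from each cohort sample are mapped onto an insertion-bearing
target (the pseudohaplotype carrying the NUI, realized here as the reference
with the final NUI set spliced in), per-NUI depth and consensus are measured,
and presence is called at ≥80% position coverage and ≥90% consensus identity.
Presence frequencies feed the MAF filter that defines the common-insertion
(BICI) set; 0/1/2 occurrence coding, PCA and UPGMA clustering summarize
population structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import linkage, to_tree
from scipy.spatial.distance import pdist

from .io_formats import DEFAULT_PARAMS, GenomeSequence, Interval, PipelineParams
from .kmer_align import KmerIndex, map_reads_batch


@dataclass(frozen=True)
class GenotypeCall:
    sample: str
    nui_id: str
    covered_fraction: float
    consensus_identity: float
    present: bool


@dataclass
class GenotypeMatrix:
    """samples × NUIs presence matrix with per-cell evidence."""

    samples: list                  # sample ids, sorted
    nui_ids: list                  # NUI ids, sorted
    presence: np.ndarray           # bool
    covered: np.ndarray            # float
    identity: np.ndarray           # float
    breed: dict = field(default_factory=dict)

    def __post_init__(self):
        ns, nn = len(self.samples), len(self.nui_ids)
        for arr in (self.presence, self.covered, self.identity):
            if arr.shape != (ns, nn):
                raise ValueError("matrix incomplete: every cell must be called")


@dataclass
class OccurrenceMatrix:
    assemblies: list
    nui_ids: list
    values: np.ndarray             # {0,1,2}

    def __post_init__(self):
        if not np.isin(self.values, (0, 1, 2)).all():
            raise ValueError("occurrence values must be 0, 1 or 2")


# ---------------------------------------------------------------------------
# Panel construction and per-sample genotyping
# ---------------------------------------------------------------------------

def build_nui_panel(reference: list[GenomeSequence], nuis,
                    ) -> tuple[list[GenomeSequence], dict]:
    """Reference with every NUI spliced at its breakpoint — the union
    pseudohaplotype the cohort reads are genotyped against.  Returns
    (panel sequences, {nui_id: Interval on panel})."""
    by_chrom: dict[str, list] = {}
    for nui in nuis:
        by_chrom.setdefault(nui.ref_breakpoint.chrom, []).append(nui)
    panel = []
    intervals: dict[str, Interval] = {}
    for chrom in reference:
        todo = sorted(by_chrom.get(chrom.name, []),
                      key=lambda n: (n.ref_breakpoint.start, n.id))
        parts = []
        prev = 0
        offset = 0
        for nui in todo:
            bp = nui.ref_breakpoint.start
            parts.append(chrom.seq[prev:bp])
            start = bp + offset
            intervals[nui.id] = Interval(chrom.name, start, start + len(nui.seq))
            parts.append(nui.seq)
            offset += len(nui.seq)
            prev = bp
        parts.append(chrom.seq[prev:])
        panel.append(GenomeSequence(chrom.name, "".join(parts)))
    return panel, intervals


def pileup_consensus(reads_r1: np.ndarray, reads_r2: np.ndarray,
                     panel_index: KmerIndex,
                     params: PipelineParams = DEFAULT_PARAMS,
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Depth and majority-consensus codes over the panel from one sample's
    reads (ties resolved toward the panel base)."""
    L = reads_r1.shape[1]
    n_pos = len(panel_index.cat)
    base_counts = np.zeros((4, n_pos), np.int32)
    col = np.arange(L)
    for mat in (reads_r1, reads_r2):
        res = map_reads_batch(mat, panel_index, params.map_accept_fraction)
        sel = np.nonzero(res["mapped"])[0]
        for b0 in range(0, len(sel), 100_000):
            s = sel[b0:b0 + 100_000]
            pos = res["cat_pos"][s][:, None] + col
            rd = mat[s]
            flip = res["strand"][s] == -1
            if flip.any():
                rc = np.where(rd[flip][:, ::-1] == 4, np.uint8(4),
                              (3 - rd[flip][:, ::-1]).astype(np.uint8))
                rd = rd.copy()
                rd[flip] = rc
            ok = rd != 4
            np.add.at(base_counts, (rd[ok].astype(np.int64), pos[ok]), 1)
    depth = base_counts.sum(0)
    best = base_counts.argmax(0).astype(np.uint8)
    # tie toward the panel base
    panel_base = panel_index.cat
    top = base_counts.max(0)
    safe = np.minimum(panel_base, 3).astype(np.int64)
    panel_count = base_counts[safe, np.arange(n_pos)]
    consensus = np.where((panel_count == top) & (panel_base != 4), panel_base, best)
    return depth, consensus


def genotype_nui(depth: np.ndarray, consensus: np.ndarray,
                 panel_index: KmerIndex, nui_iv: Interval,
                 sample: str, nui_id: str,
                 params: PipelineParams = DEFAULT_PARAMS) -> GenotypeCall:
    """Presence call for one NUI interval from a sample's pileup: position
    coverage ≥ genotype_coverage and consensus identity ≥ genotype_identity
    over covered positions."""
    if len(nui_iv) == 0:
        raise ValueError("zero-length NUI interval")
    seq_i = panel_index.names.index(nui_iv.chrom)
    lo = int(panel_index.starts[seq_i])
    d = depth[lo + nui_iv.start: lo + nui_iv.end]
    c = consensus[lo + nui_iv.start: lo + nui_iv.end]
    ref = panel_index.cat[lo + nui_iv.start: lo + nui_iv.end]
    covered = d >= 1
    covered_fraction = float(covered.mean())
    if covered.any():
        ident = float((c[covered] == ref[covered]).mean())
    else:
        ident = 0.0
    present = (covered_fraction >= params.genotype_coverage
               and ident >= params.genotype_identity)
    return GenotypeCall(sample, nui_id, covered_fraction, ident, present)


def genotype_sample(sample: str, reads, panel_index: KmerIndex,
                    nui_intervals: dict,
                    params: PipelineParams = DEFAULT_PARAMS) -> list[GenotypeCall]:
    depth, consensus = pileup_consensus(reads.r1, reads.r2, panel_index, params)
    return [genotype_nui(depth, consensus, panel_index, iv, sample, nid, params)
            for nid, iv in sorted(nui_intervals.items())]


# ---------------------------------------------------------------------------
# Matrix assembly and MAF filtering
# ---------------------------------------------------------------------------

def build_matrix(cohort_calls: dict, breed: dict | None = None) -> GenotypeMatrix:
    """Consolidate per-sample call lists into a complete matrix with
    deterministic (sorted) sample and NUI order."""
    samples = sorted(cohort_calls)
    nui_ids = sorted({c.nui_id for calls in cohort_calls.values() for c in calls})
    ns, nn = len(samples), len(nui_ids)
    presence = np.zeros((ns, nn), bool)
    covered = np.full((ns, nn), np.nan)
    identity = np.full((ns, nn), np.nan)
    col = {n: j for j, n in enumerate(nui_ids)}
    for i, s in enumerate(samples):
        for c in cohort_calls[s]:
            j = col[c.nui_id]
            presence[i, j] = c.present
            covered[i, j] = c.covered_fraction
            identity[i, j] = c.consensus_identity
    if np.isnan(covered).any():
        missing = [(samples[i], nui_ids[j]) for i, j in zip(*np.nonzero(np.isnan(covered)))]
        raise ValueError(f"missing genotype cells: {missing[:5]}")
    return GenotypeMatrix(samples, nui_ids, presence, covered, identity,
                          dict(breed or {}))


def maf_filter(matrix: GenotypeMatrix,
               params: PipelineParams = DEFAULT_PARAMS) -> list[str]:
    """Common-insertion ids: sample-level presence frequency f gives
    MAF = min(f, 1−f); keep MAF ≥ maf_min.  Monomorphic columns (f ∈ {0,1})
    are always excluded."""
    f = matrix.presence.mean(axis=0)
    maf = np.minimum(f, 1.0 - f)
    keep = (maf >= params.maf_min) & (f > 0.0) & (f < 1.0)
    return [n for n, k in zip(matrix.nui_ids, keep) if k]


def occurrence_matrix(occurrence: dict, assemblies: list, nui_ids: list,
                      ) -> OccurrenceMatrix:
    """0/1/2 coding of per-assembly pseudohaplotype occupancy.

    `occurrence[nui_id]` is a set of (assembly, haplotype-index) carriers, as
    produced by the discovery merge."""
    values = np.zeros((len(assemblies), len(nui_ids)), np.int8)
    for j, nid in enumerate(nui_ids):
        for (sample, hap) in occurrence.get(nid, ()):
            if sample in assemblies:
                i = assemblies.index(sample)
                values[i, j] = min(2, values[i, j] + 1)
    return OccurrenceMatrix(list(assemblies), list(nui_ids), values)


# ---------------------------------------------------------------------------
# Population structure
# ---------------------------------------------------------------------------

def pca(matrix: np.ndarray, n_components: int | None = None,
        ) -> tuple[np.ndarray, np.ndarray]:
    """PCA by eigendecomposition of the covariance of the centered (not
    scaled) matrix; constant columns are dropped.  Returns (scores,
    explained-variance fractions summing to 1 over retained components)."""
    X = np.asarray(matrix, dtype=float)
    keep = X.std(axis=0) > 0
    X = X[:, keep]
    if X.shape[1] == 0:
        raise ValueError("matrix has no variable columns")
    Xc = X - X.mean(axis=0)
    cov = np.cov(Xc, rowvar=False)
    cov = np.atleast_2d(cov)
    vals, vecs = np.linalg.eigh(cov)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    vals = np.clip(vals, 0.0, None)
    rank = min(X.shape[0] - 1, X.shape[1])
    rank = max(rank, 1)
    if n_components is not None:
        rank = min(rank, n_components)
    vals, vecs = vals[:rank], vecs[:, :rank]
    scores = Xc @ vecs
    evr = vals / vals.sum() if vals.sum() > 0 else vals
    return scores, evr


def hierarchical_cluster(matrix: GenotypeMatrix) -> str:
    """Average-linkage (UPGMA) tree on pairwise Jaccard distances of the
    presence profiles, serialized as Newick.  Samples are processed in
    sorted-id order so ties resolve deterministically."""
    X = matrix.presence.astype(bool)
    if len(matrix.samples) < 2:
        raise ValueError("need at least two samples to cluster")
    dist = pdist(X, metric="jaccard")
    dist = np.nan_to_num(dist, nan=0.0)
    Z = linkage(dist, method="average")
    return _to_newick(to_tree(Z), matrix.samples)


def _to_newick(node, labels: list) -> str:
    # ultrametric convention: a join at linkage distance d sits at height d/2
    def walk(n, parent_height):
        height = n.dist / 2.0
        length = max(parent_height - height, 0.0)
        if n.is_leaf():
            return f"{labels[n.id]}:{parent_height:.6f}"
        left = walk(n.left, height)
        right = walk(n.right, height)
        return f"({left},{right}):{length:.6f}"
    root_h = node.dist / 2.0
    return f"({walk(node.left, root_h)},{walk(node.right, root_h)});"
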