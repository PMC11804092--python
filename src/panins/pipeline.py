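"""End-to-end presets over the synthetic cohort.

Two desk-scale presets drive everything downstream:

* the *discovery* preset — 2 Mb reference, 5 assembled individuals, 60
  clean-context insertions of 50 bp–5 kb, 30X reads at 0.1% error — feeds the
  alignment branch, the graph branch and their intersection;
* the *genotyping* preset — a 98-sample cohort at 30X over a 200 kb
  reference with 30 insertions — feeds presence/absence genotyping, the MAF
  filter and population structure.

Each stage returns its artifacts plus truth-based metrics so the same code
serves tests, the acceptance script and the CLI.
"""

from __future__ import annotations

import numpy as np

from .io_formats import DEFAULT_PARAMS, GenomeSequence, PipelineParams
from .kmer_align import KmerIndex, ReferenceScanner
from . import synthetic_cohort as sc
from .nui_discovery import discover_sample, filter_candidates, merge_call_set
from .masking_repeats import annotate_repeats, repeat_summary, unique_bases
from .graph_pangenome import build_pangenome, extract_nonref
from .screening_intersect import best_bidirectional_hits
from .genotyping_population import (build_matrix, build_nui_panel,
                                    genotype_sample, maf_filter,
                                    occurrence_matrix, pca)


def _derive_seed(seed: int, salt: int) -> int:
    return (seed * 100_003 + salt) % (2 ** 31 - 1)


# ---------------------------------------------------------------------------
# Discovery preset
# ---------------------------------------------------------------------------

def make_discovery_cohort(seed: int = 1, n_chrom: int = 2,
                          chrom_len: int = 1_000_000, n_insertions: int = 60,
                          n_samples: int = 5, coverage: float = 30.0,
                          err_rate: float = 0.001,
                          max_insertion: int = 5000) -> dict:
    """Generate the discovery preset: reference, truth insertions, one
    assembled individual per breed with reads."""
    lib = sc.make_repeat_library(2, seed=_derive_seed(seed, 1))
    reference, repeat_truth = sc.make_reference(
        n_chrom, chrom_len, lib, repeat_density=0.30, seed=_derive_seed(seed, 2))
    size_mix = (((50, 500), 0.60), ((500, max_insertion), 0.40))
    insertions = sc.make_insertions(
        reference, lib, n_insertions, size_mix=size_mix,
        seed=_derive_seed(seed, 3), repeat_truth=repeat_truth)
    breeds = sc.DEFAULT_BREEDS[:n_samples]
    cohort = sc.make_cohort(insertions, breeds=breeds,
                            n_per_breed=(1,) * n_samples,
                            seed=_derive_seed(seed, 4))
    samples = {}
    for si, (sid, _breed) in enumerate(cohort.samples):
        h1, h2 = sc.build_pseudohaplotypes(reference, insertions,
                                           cohort.genotypes[si],
                                           cohort.hap_choice[si])
        reads = sc.simulate_reads(h1 + h2, coverage=coverage,
                                  err_rate=err_rate,
                                  seed=_derive_seed(seed, 100 + si))
        samples[sid] = {"haplotypes": (h1, h2), "reads": reads}
    return {"library": lib, "reference": reference, "repeat_truth": repeat_truth,
            "insertions": insertions, "cohort": cohort, "samples": samples}


def run_discovery(data: dict, params: PipelineParams = DEFAULT_PARAMS) -> dict:
    """Alignment-branch discovery over the preset; returns the merged NUI
    set, occurrence, and truth-based recall/precision/breakpoint metrics."""
    reference = data["reference"]
    ref_index = KmerIndex(reference, k=params.mash_k)
    scanner = ReferenceScanner(reference, k=params.mash_k)
    lib = data["library"]

    def masker(seq: str) -> int:
        return unique_bases(seq, annotate_repeats(seq, lib, params))

    per_sample = {}
    for sid, rec in data["samples"].items():
        calls = discover_sample(sid, rec["reads"], ref_index, scanner,
                                rec["haplotypes"], params)
        per_sample[sid] = filter_candidates(calls, ref_index, [], [], masker,
                                            params)
    nuis, occurrence = merge_call_set(per_sample, params)
    metrics = score_discovery(nuis, data)
    return {"nuis": nuis, "occurrence": occurrence, "per_sample": per_sample,
            "metrics": metrics, "ref_index": ref_index, "scanner": scanner}


def score_discovery(nuis, data: dict, slop: int = 5) -> dict:
    """Recall / precision / breakpoint accuracy of a call set against the
    preset truth (carried insertions only)."""
    cohort = data["cohort"]
    insertions = data["insertions"]
    carried = [ins for j, ins in enumerate(insertions)
               if (cohort.genotypes[:, j] > 0).any()]
    calls = [(n.ref_breakpoint.chrom, n.ref_breakpoint.start, n.seq) for n in nuis]
    n_exact = 0
    n_within = 0
    matched_calls = set()
    for ins in carried:
        chrom, bp = ins.ref_breakpoint.chrom, ins.ref_breakpoint.start
        best = None
        for idx, (c, p, s) in enumerate(calls):
            if c == chrom and abs(p - bp) <= slop:
                d = abs(p - bp)
                if best is None or d < best[0]:
                    best = (d, idx)
        if best is not None:
            matched_calls.add(best[1])
            n_within += 1
            if best[0] == 0:
                n_exact += 1
    recall = n_within / len(carried) if carried else 1.0
    precision = len(matched_calls) / len(calls) if calls else 1.0
    return {"n_truth_carried": len(carried), "n_calls": len(calls),
            "recall": recall, "precision": precision,
            "breakpoint_exact_fraction": n_exact / n_within if n_within else 0.0,
            "breakpoint_within_slop_fraction": n_within / len(carried) if carried else 1.0}


# ---------------------------------------------------------------------------
# Graph branch on the same preset
# ---------------------------------------------------------------------------

def run_graph(data: dict, params: PipelineParams = DEFAULT_PARAMS) -> dict:
    assemblies = {}
    for sid, rec in data["samples"].items():
        h1, h2 = rec["haplotypes"]
        assemblies[f"{sid}_h1"] = h1
        assemblies[f"{sid}_h2"] = h2
    graph, stats, order = build_pangenome(data["reference"], assemblies, params)
    nonref = extract_nonref(graph, params=params)
    cohort, insertions = data["cohort"], data["insertions"]
    carried = [ins for j, ins in enumerate(insertions)
               if (cohort.genotypes[:, j] > 0).any()]
    target = [ins for ins in carried if len(ins.seq) >= 100]
    nonref_seqs = {s.seq for s in nonref}
    recovered = sum(1 for ins in target if ins.seq in nonref_seqs)
    metrics = {"n_nonref_segments": len(nonref),
               "n_truth_carried_ge100": len(target),
               "recovery": recovered / len(target) if target else 1.0}
    return {"graph": graph, "stats": stats, "order": order,
            "nonref": nonref, "metrics": metrics}


# ---------------------------------------------------------------------------
# Intersection of the two branches
# ---------------------------------------------------------------------------

def run_intersection(discovery: dict, graph: dict, data: dict,
                     params: PipelineParams = DEFAULT_PARAMS) -> dict:
    set_a = [GenomeSequence(n.id, n.seq) for n in discovery["nuis"]]
    set_b = [GenomeSequence(s.name, s.seq) for s in graph["nonref"]]
    pairs, final_ids = best_bidirectional_hits(set_a, set_b, params)
    final = [n for n in discovery["nuis"] if n.id in set(final_ids)]
    cohort, insertions = data["cohort"], data["insertions"]
    carried = [ins for j, ins in enumerate(insertions)
               if (cohort.genotypes[:, j] > 0).any()]
    # truth insertions recovered in the intersected (final) set
    final_keys = {(n.ref_breakpoint.chrom, n.ref_breakpoint.start) for n in final}
    # graph segments are callable at >50 bp only
    target = [i for i in carried if len(i.seq) > params.graph_min_segment]
    recovered = sum(1 for i in target
                    if (i.ref_breakpoint.chrom, i.ref_breakpoint.start) in final_keys)
    return {"pairs": pairs, "final_nuis": final,
            "metrics": {"n_pairs": len(pairs), "n_final": len(final),
                        "n_truth": len(target),
                        "recovery": recovered / len(target) if target else 1.0,
                        "final_bp": sum(len(n.seq) for n in final)}}


# ---------------------------------------------------------------------------
# Genotyping preset
# ---------------------------------------------------------------------------

def make_genotyping_cohort(seed: int = 1, chrom_len: int = 200_000,
                           n_insertions: int = 30, coverage: float = 30.0,
                           n_per_breed=(20, 19, 20, 20, 19),
                           err_rate: float = 0.001,
                           freq_model=None) -> dict:
    """98-sample cohort over a compact reference for genotyping work."""
    lib = sc.make_repeat_library(2, seed=_derive_seed(seed, 11))
    reference, repeat_truth = sc.make_reference(
        1, chrom_len, lib, repeat_density=0.30, seed=_derive_seed(seed, 12))
    insertions = sc.make_insertions(
        reference, lib, n_insertions,
        size_mix=(((50, 500), 0.7), ((500, 2000), 0.3)),
        seed=_derive_seed(seed, 13), repeat_truth=repeat_truth, min_spacing=2000)
    cohort = sc.make_cohort(insertions, n_per_breed=n_per_breed,
                            freq_model=freq_model, seed=_derive_seed(seed, 14))
    return {"library": lib, "reference": reference, "insertions": insertions,
            "cohort": cohort, "coverage": coverage, "err_rate": err_rate,
            "seed": seed}


def run_genotyping(data: dict, params: PipelineParams = DEFAULT_PARAMS) -> dict:
    """Genotype the cohort against the truth-NUI panel and apply the MAF
    filter; reports accuracy against the cohort truth."""
    reference, insertions, cohort = (data["reference"], data["insertions"],
                                     data["cohort"])
    panel, intervals = build_nui_panel(reference, insertions)
    panel_index = KmerIndex(panel, k=params.mash_k)
    cohort_calls = {}
    breed = {}
    for si, (sid, br) in enumerate(cohort.samples):
        h1, h2 = sc.build_pseudohaplotypes(reference, insertions,
                                           cohort.genotypes[si],
                                           cohort.hap_choice[si])
        reads = sc.simulate_reads(h1 + h2, coverage=data["coverage"],
                                  err_rate=data["err_rate"],
                                  seed=_derive_seed(data["seed"], 1000 + si))
        cohort_calls[sid] = genotype_sample(sid, reads, panel_index,
                                            intervals, params)
        breed[sid] = br
    matrix = build_matrix(cohort_calls, breed)
    bicis = maf_filter(matrix, params)
    # truth comparison
    order = [sid for sid, _ in cohort.samples]
    row = {sid: i for i, sid in enumerate(order)}
    ins_col = {ins.id: j for j, ins in enumerate(insertions)}
    truth_present = np.zeros_like(matrix.presence)
    for i, sid in enumerate(matrix.samples):
        for j, nid in enumerate(matrix.nui_ids):
            truth_present[i, j] = cohort.genotypes[row[sid], ins_col[nid]] > 0
    accuracy = float((matrix.presence == truth_present).mean())
    tf = truth_present.mean(axis=0)
    tmaf = np.minimum(tf, 1 - tf)
    truth_bici = {nid for nid, m, f in zip(matrix.nui_ids, tmaf, tf)
                  if m >= params.maf_min and 0.0 < f < 1.0}
    agree = sum(1 for nid in matrix.nui_ids
                if (nid in truth_bici) == (nid in set(bicis)))
    return {"matrix": matrix, "bicis": bicis, "panel": panel,
            "intervals": intervals,
            "metrics": {"genotype_accuracy": accuracy,
                        "n_nuis": len(matrix.nui_ids),
                        "n_bicis": len(bicis),
                        "maf_agreement": agree / len(matrix.nui_ids)}}


# ---------------------------------------------------------------------------
# Population structure on a breed-structured cohort
# ---------------------------------------------------------------------------

def breed_separation_pca(seed: int = 1, n_insertions: int = 60,
                         offset: float = 0.4) -> dict:
    """PCA of a breed-structured 0/1/2 genotype matrix; reports the ratio of
    inter-breed centroid distance to intra-breed spread in PC1–2."""
    rng_seed = _derive_seed(seed, 21)
    lib = sc.make_repeat_library(1, seed=rng_seed)
    reference, rt = sc.make_reference(1, 150_000, lib, 0.2,
                                      seed=_derive_seed(seed, 22))
    insertions = sc.make_insertions(reference, lib, n_insertions,
                                    size_mix=(((50, 300), 1.0),),
                                    seed=_derive_seed(seed, 23),
                                    repeat_truth=rt, min_spacing=1000)
    cohort = sc.make_cohort(insertions,
                            freq_model=sc.structured_freq_model(offset),
                            seed=_derive_seed(seed, 24))
    X = cohort.genotypes.astype(float)
    scores, evr = pca(X)
    pc = scores[:, :2]
    breeds = [b for _s, b in cohort.samples]
    uniq = sorted(set(breeds))
    cents = {b: pc[[i for i, bb in enumerate(breeds) if bb == b]].mean(axis=0)
             for b in uniq}
    inter = np.mean([np.linalg.norm(cents[a] - cents[b])
                     for i, a in enumerate(uniq) for b in uniq[i + 1:]])
    intra = np.mean([np.linalg.norm(pc[i] - cents[b])
                     for i, b in enumerate(breeds)])
    return {"scores": scores, "explained": evr, "cohort": cohort,
            "inter_breed_distance": float(inter),
            "intra_breed_distance": float(intra),
            "separation_ratio": float(inter / intra) if intra else np.inf,
            "pc1_pct": percentage_0(evr[0]), "pc2_pct": percentage_0(evr[1])}


def percentage_0(frac: float) -> float:
    return round(100.0 * float(frac), 1)
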