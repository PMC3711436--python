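"""The iterative loop: step one, convergence, modes, and proofreading."""

import numpy as np
import pytest

from mitobait.assembly import Assembly, Contig
from mitobait.baiting import BaitParams, bait_reads, build_kmer_index
from mitobait.controller import (IterationState, RunConfig, initial_reference,
                                 proofread_extend, run_iterations)
from mitobait.evaluate import compare_assemblies, recruitment_metrics
from mitobait.seq_io import ReadPool, SeqRecord
from mitobait.simulate import (GenomeSpec, SimConfig, evolve_genome,
                               pool_readsets, simulate_ancestor, simulate_reads)

from conftest import random_dna, tile_reads


def _paired_pool(specs):
    """Build a fully paired pool from [(id_base, fwd_seq, rev_seq), ...]."""
    records, pairing = [], {}
    for base, f, r in specs:
        records += [SeqRecord(f"{base}/1", f), SeqRecord(f"{base}/2", r)]
        pairing[base] = (f"{base}/1", f"{base}/2")
    return ReadPool(records, pairing)


# -- step one: initial reference from a distant genome ----------------------

def test_initial_reference_with_own_genome_is_exact(toy_genome, toy_reads):
    state = initial_reference(toy_reads, toy_genome, RunConfig())
    assert len(state.assembly.contigs) == 1
    # 100% identity over covered columns (extension past the ends of the
    # linear reference representation is genuine circular sequence)
    assert state.assembly.contigs[0].seq in toy_genome.seq * 3
    assert state.count_history == [len(state.recruited_ids)]


def test_initial_reference_recovers_only_conserved_blocks(rng):
    target = random_dna(rng, 3000)
    distant = (random_dna(rng, 800) + target[500:900] + random_dna(rng, 700)
               + target[1800:2200] + random_dna(rng, 800))
    reads = ReadPool(tile_reads(target, 100, 30))
    state = initial_reference(reads, SeqRecord("distant", distant), RunConfig())
    assert len(state.assembly.contigs) >= 2
    # the two conserved blocks are covered
    joined = " ".join(c.seq for c in state.assembly.contigs)
    assert target[560:840] in joined
    assert target[1860:2140] in joined


def test_quick_mode_equals_bait_then_map(rng):
    target = random_dna(rng, 2000)
    distant = random_dna(rng, 500) + target[400:1200] + random_dna(rng, 500)
    pool = ReadPool(tile_reads(target, 100, 40))
    ref = SeqRecord("distant", distant)
    quick = initial_reference(pool, ref, RunConfig(quick=True))
    reduced = bait_reads(pool, build_kmer_index([ref], 31), BaitParams())
    plain = initial_reference(reduced, ref, RunConfig(quick=False))
    assert [c.seq for c in quick.assembly.contigs] == \
           [c.seq for c in plain.assembly.contigs]


def test_seed_too_distant_raises(rng):
    # poly-A reads cannot credibly align anywhere on an A-free reference
    pool = ReadPool([SeqRecord(f"r{i}", "A" * 100) for i in range(5)])
    far = "".join("CGT"[i] for i in rng.integers(0, 3, size=1000))
    with pytest.raises(ValueError, match="seed too distant"):
        initial_reference(pool, SeqRecord("far", far), RunConfig())


# -- convergence and the two assembly modes ---------------------------------

def test_true_genome_seed_is_stationary_within_two_iterations(toy_genome):
    reads = simulate_reads(toy_genome, SimConfig(150, 350, 40, 800,
                                                 linear=True, rng_seed=5))
    report = run_iterations(reads, toy_genome, RunConfig())
    assert report.converged
    assert report.iterations_used == 2
    assert report.count_history[0] == report.count_history[1] == len(reads.records)
    diff = compare_assemblies(max(report.assembly.contigs, key=len), toy_genome)
    assert diff.identity_pct == 100.0


def test_barcode_seed_recovers_full_circular_genome(toy_genome, toy_reads):
    seed = SeqRecord("coi", toy_genome.seq[800:1450])  # ~650 bp barcode
    report = run_iterations(toy_reads, seed, RunConfig())
    assert report.converged
    assert len(report.assembly.contigs) == 1
    contig = report.assembly.contigs[0]
    assert contig.circular
    diff = compare_assemblies(contig, toy_genome, circular=True)
    assert (diff.substitutions, diff.indels) == (0, 0)
    assert diff.identity_pct == 100.0


def test_denovo_pair_rescue_converges_in_fewer_iterations(toy_genome, toy_reads):
    seed = SeqRecord("coi", toy_genome.seq[800:1450])
    mapping = run_iterations(toy_reads, seed, RunConfig(mode="mapping"))
    denovo = run_iterations(toy_reads, seed,
                            RunConfig(mode="denovo",
                                      bait=BaitParams(pair_rescue=True)))
    assert mapping.converged and denovo.converged
    assert denovo.iterations_used < mapping.iterations_used
    diff = compare_assemblies(max(denovo.assembly.contigs, key=len),
                              toy_genome, circular=True)
    assert diff.identity_pct == 100.0


def test_recruited_count_monotone_and_bounded(toy_genome, toy_reads):
    seed = SeqRecord("coi", toy_genome.seq[0:700])
    report = run_iterations(toy_reads, seed, RunConfig())
    counts = report.count_history
    assert all(b >= a for a, b in zip(counts, counts[1:]))
    assert counts[-1] <= len(toy_reads.records)


def test_iteration_cap_reports_unconverged(toy_genome, toy_reads):
    seed = SeqRecord("coi", toy_genome.seq[0:700])
    report = run_iterations(toy_reads, seed, RunConfig(max_iterations=3))
    assert not report.converged
    assert report.iterations_used == 3
    assert report.assembly.contigs  # partial result still produced
    assert any("max_iterations" in n for n in report.notes)


@pytest.mark.parametrize("trial", [0, 1])
def test_any_long_seed_substring_recovers_the_genome(trial):
    """Self-recovery: any >=200 bp exact seed of a repeat-free genome with
    error-free paired reads leads to the complete circle at 100% identity."""
    rng = np.random.default_rng(50 + trial)
    genome = SeqRecord("g", simulate_ancestor(
        GenomeSpec(2500, 0.55, rng_seed=60 + trial)).seq)
    reads = simulate_reads(genome, SimConfig(150, 350, 40, 700,
                                             rng_seed=70 + trial))  # ~42x
    start = int(rng.integers(0, 2500 - 250))
    seed = SeqRecord("seed", genome.seq[start:start + 250])
    report = run_iterations(reads, seed, RunConfig())
    diff = compare_assemblies(max(report.assembly.contigs, key=len),
                              genome, circular=True)
    assert diff.identity_pct == 100.0
    assert diff.length_pct == 100.0


# -- proofreading mode -------------------------------------------------------

@pytest.fixture
def pr_genome(rng):
    return random_dna(np.random.default_rng(80), 1000)


def _pr_state(genome, a=200, b=600):
    return IterationState(0, Assembly([Contig("ref", genome[a:b])]))


def test_proofread_perfect_anchor_extends_reference(pr_genome):
    g = pr_genome
    pool = _paired_pool([("p1", g[250:350], g[560:660])])
    state = proofread_extend(_pr_state(g), pool, RunConfig(proofread=True))
    assert state.count_history == [2]  # both mates incorporated
    ref = state.assembly.contigs[0].seq
    assert ref == g[200:660]  # extended right by the mate's overhang


def test_proofread_single_mismatch_blocks_incorporation(pr_genome):
    g = pr_genome
    mate1 = g[250:350]
    mate1 = mate1[:50] + ("A" if mate1[50] != "A" else "C") + mate1[51:]
    pool = _paired_pool([("p1", mate1, g[700:800])])
    state = proofread_extend(_pr_state(g), pool, RunConfig(proofread=True))
    assert state.count_history == [0]
    assert state.assembly.contigs[0].seq == g[200:600]


def test_proofread_rejects_discordant_heterospecific_pair(pr_genome):
    g = pr_genome
    bad_mate = g[560:600] + random_dna(np.random.default_rng(81), 60)
    # mismatch at overlap position 35: a 35 bp exact stretch still anchors
    # the read, so the conflict is visible rather than merely un-anchored
    bad_mate = bad_mate[:35] + ("A" if bad_mate[35] != "A" else "C") + bad_mate[36:]
    pool = _paired_pool([
        ("t1", g[250:350], g[560:660]),   # genuine pair
        ("f1", g[300:400], bad_mate),     # perfect anchor, conflicting mate
    ])
    state = proofread_extend(_pr_state(g), pool, RunConfig(proofread=True))
    engine = state.cache["proofread_engine"]
    assert engine.fp_avoided == 1
    assert state.count_history == [2]  # only the genuine pair incorporated
    assert state.assembly.contigs[0].seq == g[200:660]


def test_proofread_halts_on_conflicting_unanimous_extensions(pr_genome):
    """Two species extending a shared block differently: no commit, halt."""
    g = pr_genome
    variant = g[560:600] + random_dna(np.random.default_rng(82), 60)
    pool = _paired_pool([
        ("t1", g[250:350], g[560:660]),
        ("t2", g[260:360], g[560:660]),
        ("f1", g[250:350], variant),
        ("f2", g[260:360], variant),
    ])
    state = proofread_extend(_pr_state(g), pool, RunConfig(proofread=True))
    engine = state.cache["proofread_engine"]
    assert engine.halted_right
    assert state.assembly.contigs[0].seq == g[200:600]  # nothing committed


def test_proofread_requires_fully_paired_pool(pr_genome):
    g = pr_genome
    pool = ReadPool([SeqRecord("solo", g[250:350])])
    with pytest.raises(ValueError, match="paired"):
        proofread_extend(_pr_state(g), pool, RunConfig(proofread=True))


def test_proofread_requires_single_contig_reference(pr_genome):
    g = pr_genome
    state = IterationState(0, Assembly([Contig("a", g[:300]), Contig("b", g[400:700])]))
    pool = _paired_pool([("p1", g[50:150], g[500:600])])
    with pytest.raises(ValueError, match="single"):
        proofread_extend(state, pool, RunConfig(proofread=True))


def test_proofread_separates_two_pooled_genomes():
    """A two-genome pooled sample: each barcode-seeded proofreading run
    recovers its own genome with no heterospecific reads."""
    anc = simulate_ancestor(GenomeSpec(4000, 0.55, rng_seed=90))
    g1 = evolve_genome(anc, 0.065, 91, new_id="g1")
    g2 = evolve_genome(anc, 0.065, 92, new_id="g2")
    pooled = pool_readsets([
        simulate_reads(g1, SimConfig(150, 300, 50, 1400, rng_seed=93)),
        simulate_reads(g2, SimConfig(150, 300, 50, 1400, rng_seed=94)),
    ])
    for genome in (g1, g2):
        seed = SeqRecord("bc", genome.seq[1000:1800])
        report = run_iterations(pooled, seed, RunConfig(proofread=True))
        assert report.converged
        diff = compare_assemblies(max(report.assembly.contigs, key=len),
                                  genome, circular=True)
        assert diff.identity_pct == 100.0
        rec = recruitment_metrics(report.recruited_ids, pooled.provenance, genome.id)
        assert rec.fp_pct == 0.0
        assert rec.reads_pct > 99.0
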