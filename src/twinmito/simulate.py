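"""Seeded synthetic genomes and planted-truth datasets.

Every generator emulates the statistical structure of compact diatom-type
mitochondrial genomes and their dinoflagellate-type counterparts: ~60 genes
in three classes on a circular (or gapped) molecule, AT-rich composition with
a strong third-codon-position A/T bias, short intergenic spacers, gene orders
related by a small number of inversions, DNA/cDNA pairs with substitutional
editing concentrated at codon positions 1–2 (mostly A->G), split genes
rejoined in transcripts, and contigs carrying high-identity gene fragments
inside unrelated flanks.

Determinism: one integer seed drives a named pseudo-random stream per
generator stage (the stream key hashes the stage name), so adding a stage
never perturbs another stage's draws and equal seeds give byte-identical
output.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np

from .io import AnnotatedGenome, GeneFeature, reverse_complement
from .rearrangement import SignedGeneOrder

__all__ = [
    "SimulationTruth",
    "stream",
    "simulate_genome",
    "apply_random_reversals",
    "simulate_editing_pair",
    "simulate_pseudogene_set",
    "simulate_structural_events",
    "simulate_trans_splice",
]

PROTEIN_NAMES = [
    "cox1", "cox2", "cox3", "cob", "atp6", "atp8", "atp9", "tatc",
    "nad1", "nad2", "nad3", "nad4", "nad4l", "nad5", "nad6", "nad7",
    "nad9", "nad11", "rps2", "rps3", "rps4", "rps7", "rps8", "rps10",
    "rps11", "rps12", "rps13", "rps14", "rps19", "rpl2", "rpl5", "rpl6",
    "rpl16", "rpl14", "rpl31",
]
RRNA_NAMES = ["rnl", "rns"]
TRNA_AMINO = "ACDEFGHIKLMNPQRSVWY"

STOP_CODONS = ("TAA", "TAG", "TGA")


def stream(seed: int, stage: str) -> np.random.Generator:
    """Named pseudo-random stream: one per generator stage."""
    return np.random.default_rng([int(seed) % (2**31), zlib.crc32(stage.encode())])


@dataclass
class SimulationTruth:
    """Ground truth of one simulation run (fields used vary by generator)."""

    seed: int
    params: dict = field(default_factory=dict)
    gene_lengths: dict[str, int] = field(default_factory=dict)
    spacer_lengths: list[int] = field(default_factory=list)
    reversals: list[tuple[int, int]] = field(default_factory=list)
    edit_sites: list[tuple[int, str, str]] = field(default_factory=list)
    events: dict = field(default_factory=dict)
    fragments: list[dict] = field(default_factory=list)


# ---------------------------------------------------------------------------
# sequence building blocks
# ---------------------------------------------------------------------------

def _random_dna(rng: np.random.Generator, length: int, gc: float) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=length, p=p)])


def _random_cds(rng: np.random.Generator, n_codons: int, gc: float,
                third_at: float) -> str:
    """A stop-free CDS: ATG + internal codons + one stop codon.

    Codon positions 1–2 follow the genomic GC, position 3 carries the A/T
    bias typical of AT-rich organellar genomes.
    """
    p12 = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    p3 = [third_at / 2, (1 - third_at) / 2, (1 - third_at) / 2, third_at / 2]
    bases = np.array(list("ACGT"))
    codons = []
    while len(codons) < n_codons - 2:
        c = (bases[rng.choice(4, p=p12)] + bases[rng.choice(4, p=p12)]
             + bases[rng.choice(4, p=p3)])
        if c not in STOP_CODONS:
            codons.append(c)
    stop = ("TAA", "TAG")[rng.integers(2)]
    return "ATG" + "".join(codons) + stop


def _mutate(rng: np.random.Generator, seq: str, rate: float,
            protect: set[int] | None = None) -> str:
    """Substitution-only mutation at the given per-base rate."""
    out = list(seq)
    n_mut = rng.binomial(len(seq), rate)
    positions = rng.choice(len(seq), size=min(n_mut, len(seq)), replace=False)
    for pos in positions:
        if protect and int(pos) in protect:
            continue
        alternatives = [b for b in "ACGT" if b != out[pos]]
        out[pos] = alternatives[rng.integers(3)]
    return "".join(out)


def _assemble(plan: list[tuple[str, str, str, str]], topology: str,
              gc: float, spacer_mean: float, rng: np.random.Generator,
              genome_id: str) -> tuple[AnnotatedGenome, list[int]]:
    """Concatenate (name, cls, strand, spliced_seq) entries with random
    spacers into an annotated genome. The last spacer closes the circle for
    circular topology and is omitted for linear genomes."""
    parts: list[str] = []
    features: list[GeneFeature] = []
    spacers: list[int] = []
    pos = 1
    n_genes = len(plan)
    for i, (name, cls, strand, seq) in enumerate(plan):
        genomic = reverse_complement(seq) if strand == "-" else seq
        features.append(GeneFeature(name, cls, strand,
                                    [(pos, pos + len(seq) - 1)]))
        parts.append(genomic)
        pos += len(seq)
        last = i == n_genes - 1
        if not (last and topology != "circular"):
            spacer = int(rng.exponential(spacer_mean))
            spacers.append(spacer)
            parts.append(_random_dna(rng, spacer, gc))
            pos += spacer
    genome = AnnotatedGenome(genome_id, topology, "".join(parts), features)
    return genome, spacers


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------

def simulate_genome(n_genes: int = 58,
                    class_mix: tuple[float, float, float] = (0.57, 0.035, 0.395),
                    protein_len_mean: float = 790.0,
                    protein_len_sd: float = 240.0,
                    spacer_mean: float = 58.0,
                    gc: float = 0.31,
                    third_position_at: float = 0.79,
                    topology: str = "circular",
                    genome_id: str = "sim",
                    seed: int = 0) -> tuple[AnnotatedGenome, SimulationTruth]:
    """Generate a compact organellar genome with full ground truth.

    Defaults are sized to a diatom-type mitochondrial genome: ~58 genes with
    a protein/rRNA/tRNA mix near 33/2/23, mean protein gene ~790 nt, mean
    spacer ~58 nt, GC ~31%, third-codon-position A+T ~79%.
    """
    if abs(sum(class_mix) - 1) > 1e-6:
        raise ValueError("class_mix must sum to 1")
    rng = stream(seed, f"genome:{genome_id}")
    n_prot = int(round(n_genes * class_mix[0]))
    n_rrna = min(int(round(n_genes * class_mix[1])), len(RRNA_NAMES))
    n_trna = n_genes - n_prot - n_rrna
    if n_trna < 0 or n_prot > len(PROTEIN_NAMES) + 50 or n_trna > 2 * len(TRNA_AMINO):
        raise ValueError("infeasible gene-class mix for the name pools")
    plan: list[tuple[str, str, str, str]] = []
    names: list[str] = []
    for i in range(n_prot):
        names.append(PROTEIN_NAMES[i] if i < len(PROTEIN_NAMES)
                     else f"gene{i - len(PROTEIN_NAMES) + 1}")
    truth = SimulationTruth(seed=seed, params={
        "n_genes": n_genes, "class_mix": class_mix, "gc": gc,
        "protein_len_mean": protein_len_mean, "spacer_mean": spacer_mean,
        "third_position_at": third_position_at, "topology": topology,
    })
    for name in names:
        n_codons = max(50, int(round(rng.normal(protein_len_mean / 3,
                                                protein_len_sd / 3))))
        seq = _random_cds(rng, n_codons, gc, third_position_at)
        plan.append((name, "protein", "+", seq))
    for name, length in zip(RRNA_NAMES[:n_rrna], (2850, 1480)):
        length = int(length * rng.uniform(0.95, 1.05))
        plan.append((name, "rRNA", "+", _random_dna(rng, length, gc + 0.05)))
    for i in range(n_trna):
        amino = TRNA_AMINO[i % len(TRNA_AMINO)]
        name = f"trn{amino.lower()}" + ("" if i < len(TRNA_AMINO) else "2")
        length = int(rng.integers(71, 90))
        plan.append((name, "tRNA", "+", _random_dna(rng, length, gc + 0.12)))
    order = rng.permutation(len(plan))
    plan = [plan[i] for i in order]
    plan = [(name, cls, ("+" if rng.random() < 0.5 else "-"), seq)
            for name, cls, _, seq in plan]
    genome, spacers = _assemble(plan, topology, gc, spacer_mean, rng, genome_id)
    truth.gene_lengths = {name: len(seq) for name, _, _, seq in plan}
    truth.spacer_lengths = spacers
    truth.params["plan"] = [(n, c, s) for n, c, s, _ in plan]
    return genome, truth


def apply_random_reversals(order: SignedGeneOrder, k: int, seed: int = 0
                           ) -> tuple[SignedGeneOrder, SimulationTruth]:
    """Apply k uniformly chosen signed interval reversals to a gene order."""
    rng = stream(seed, "reversals")
    signs = {"+": 1, "-": -1}
    values = [signs[s] for _, s in order.entries]
    entries = list(order.entries)
    truth = SimulationTruth(seed=seed)
    n = len(entries)
    for _ in range(int(k)):
        i, j = sorted(rng.integers(0, n, size=2))
        truth.reversals.append((int(i), int(j)))
        entries[i:j + 1] = [(name, "-" if s == "+" else "+")
                            for name, s in entries[i:j + 1][::-1]]
    new_order = SignedGeneOrder(order.genome_id + f"_rev{k}", entries,
                                order.topology)
    return new_order, truth


def simulate_editing_pair(cds: str, n_sites: int,
                          type_weights: dict[str, float] | None = None,
                          codon_pos_weights: tuple[float, float, float]
                          = (0.45, 0.45, 0.10),
                          seed: int = 0) -> tuple[str, SimulationTruth]:
    """Plant exactly ``n_sites`` substitutional edits into a transcript copy
    of ``cds``; no indels.

    Default substitution weights follow the dinoflagellate editing spectrum
    (A->G dominant, then T->C and C->T, occasionally G->C) and edits fall
    mostly at codon positions 1–2.
    """
    if type_weights is None:
        type_weights = {"A>G": 0.70, "T>C": 0.15, "C>T": 0.10, "G>C": 0.05}
    cds = cds.upper()
    rng = stream(seed, "editing")
    types = list(type_weights)
    probs = np.array([type_weights[t] for t in types], dtype=float)
    probs /= probs.sum()
    cpw = np.array(codon_pos_weights, dtype=float)
    cpw /= cpw.sum()
    candidates: dict[tuple[str, int], list[int]] = {}
    for pos in range(len(cds)):
        codon_pos = pos % 3 + 1
        candidates.setdefault((cds[pos], codon_pos), []).append(pos)
    transcript = list(cds)
    truth = SimulationTruth(seed=seed)
    used: set[int] = set()
    attempts = 0
    while len(truth.edit_sites) < n_sites:
        attempts += 1
        if attempts > 100 * max(n_sites, 1):
            raise ValueError("cannot place requested edit sites on this CDS")
        sub = types[rng.choice(len(types), p=probs)]
        codon_pos = int(rng.choice(3, p=cpw)) + 1
        pool = [p for p in candidates.get((sub[0], codon_pos), [])
                if p not in used]
        if not pool:
            continue
        pos = int(pool[rng.integers(len(pool))])
        used.add(pos)
        transcript[pos] = sub[2]
        truth.edit_sites.append((pos + 1, sub[0], sub[2]))
    truth.edit_sites.sort()
    return "".join(transcript), truth


def simulate_pseudogene_set(gene: str, n_fragments: int,
                            span_range: tuple[int, int] = (100, 400),
                            identity_levels: tuple[float, ...] = (1.0, 0.97, 0.92),
                            flank_range: tuple[int, int] = (50, 150),
                            flank_gc: float = 0.30,
                            seed: int = 0
                            ) -> tuple[dict[str, str], SimulationTruth]:
    """Contigs carrying one gene fragment each inside unrelated flanks.

    Fragment spans are drawn uniformly along the gene, identities from
    ``identity_levels``, orientations at random; flanks are random DNA.
    """
    rng = stream(seed, "pseudogenes")
    gene = gene.upper()
    fragments: dict[str, str] = {}
    truth = SimulationTruth(seed=seed)
    for i in range(int(n_fragments)):
        lo, hi = span_range
        span = int(rng.integers(lo, min(hi, len(gene)) + 1))
        start = int(rng.integers(0, len(gene) - span + 1))
        core = gene[start:start + span]
        identity = float(identity_levels[rng.integers(len(identity_levels))])
        mutated = _mutate(rng, core, 1.0 - identity)
        realized = sum(a == b for a, b in zip(core, mutated)) / span
        core = mutated
        orientation = "+" if rng.random() < 0.5 else "-"
        left = _random_dna(rng, int(rng.integers(*flank_range)), flank_gc)
        right = _random_dna(rng, int(rng.integers(*flank_range)), flank_gc)
        # flanks are unrelated sequence: force the bases adjacent to the core
        # to differ from the gene's continuation so the planted span is the
        # true maximal match
        if left and start > 0 and left[-1] == gene[start - 1]:
            left = left[:-1] + ("C" if gene[start - 1] != "C" else "T")
        gene_next = start + span
        if right and gene_next < len(gene) and right[0] == gene[gene_next]:
            right = ("C" if gene[gene_next] != "C" else "T") + right[1:]
        assembled = left + core + right
        if orientation == "-":
            assembled = reverse_complement(assembled)
            left_len, right_len = len(right), len(left)
        else:
            left_len, right_len = len(left), len(right)
        frag_id = f"frag{i:03d}"
        fragments[frag_id] = assembled
        truth.fragments.append({
            "fragment": frag_id,
            "gene_interval": (start + 1, start + span),
            "identity": identity,
            "realized_identity": realized,
            "orientation": orientation,
            "left_flank": left_len,
            "right_flank": right_len,
        })
    return fragments, truth


def _plan_from_genome(genome: AnnotatedGenome) -> list[tuple[str, str, str, str]]:
    from .io import spliced_sequence

    return [(f.name, f.cls, f.strand, spliced_sequence(genome, f))
            for f in sorted(genome.features, key=lambda f: f.segments[0][0])]


def simulate_structural_events(genome: AnnotatedGenome, event_spec: dict,
                               seed: int = 0
                               ) -> tuple[AnnotatedGenome, SimulationTruth]:
    """Derive a genome carrying planted structural events plus ground truth.

    ``event_spec`` keys (all optional):

    * ``fission``: gene name — split that CDS at a random internal codon;
      part a keeps the prefix and gains a stop, part b gains ATG and is
      relocated to a random position on the opposite strand.
    * ``fusion``: (upstream, downstream) — replace the two CDSs by one
      in-frame CDS (upstream minus stop + downstream), named "up-down",
      keeping the downstream initiator.
    * ``insert``: {"gene", "aa_start", "aa_len"} — in-frame insertion of
      ``aa_len`` random codons after amino acid ``aa_start``.
    * ``mutate``: per-base substitution rate applied to every CDS (planted
      divergence between the two genomes).

    The modified genome is reassembled with fresh spacers; gene order is
    preserved except where an event dictates otherwise.
    """
    rng = stream(seed, "events")
    plan = _plan_from_genome(genome)
    truth = SimulationTruth(seed=seed, params={"source": genome.id})
    by_name = {name: i for i, (name, *_rest) in enumerate(plan)}

    if "colocate" in event_spec:
        # move the second gene directly after the first, same strand — the
        # precondition of a fusion scenario (partners adjacent but unfused)
        u, v = event_spec["colocate"]
        iu, iv = by_name[u], by_name[v]
        entry_u = plan[iu]
        entry_v = plan.pop(iv)
        iu = plan.index(entry_u)
        plan.insert(iu + 1, (entry_v[0], entry_v[1], entry_u[2], entry_v[3]))
        truth.events["colocate"] = (u, v)
        by_name = {name: i for i, (name, *_r) in enumerate(plan)}

    if "mutate" in event_spec:
        rate = float(event_spec["mutate"])
        plan = [(n, c, s, _mutate(rng, seq, rate) if c == "protein" else seq)
                for n, c, s, seq in plan]
        truth.events["mutate"] = rate

    if "fission" in event_spec:
        gname = event_spec["fission"]
        i = by_name[gname]
        name, cls, strand, seq = plan[i]
        n_codons = len(seq) // 3
        cut = int(rng.integers(int(n_codons * 0.3), int(n_codons * 0.7)))
        part_a = seq[:3 * cut] + "TAA"
        part_b = "ATG" + seq[3 * cut:]
        plan[i] = (f"{gname}a", cls, strand, part_a)
        other = int(rng.integers(0, len(plan)))
        flip = {"+": "-", "-": "+"}
        plan.insert(other, (f"{gname}b", cls, flip[strand], part_b))
        truth.events["fission"] = {"gene": gname, "breakpoint_aa": cut,
                                   "parts": (f"{gname}a", f"{gname}b")}
        by_name = {name: i for i, (name, *_r) in enumerate(plan)}

    if "fusion" in event_spec:
        up, down = event_spec["fusion"]
        iu, idn = by_name[up], by_name[down]
        _, cls_u, strand_u, seq_u = plan[iu]
        _, _, _, seq_d = plan[idn]
        fused = seq_u[:-3] + seq_d  # upstream loses its stop codon
        fused_name = f"{up}-{down}"
        keep_i = min(iu, idn)
        plan = [p for k, p in enumerate(plan) if k not in (iu, idn)]
        plan.insert(keep_i, (fused_name, cls_u, strand_u, fused))
        truth.events["fusion"] = {"upstream": up, "downstream": down,
                                  "fused": fused_name,
                                  "junction_aa": len(seq_u) // 3 - 1}
        by_name = {name: i for i, (name, *_r) in enumerate(plan)}

    if "insert" in event_spec:
        spec = event_spec["insert"]
        gname, aa_start, aa_len = spec["gene"], spec["aa_start"], spec["aa_len"]
        i = by_name[gname]
        name, cls, strand, seq = plan[i]
        if aa_start >= len(seq) // 3 - 1:
            raise ValueError(
                f"insert position aa {aa_start} beyond {gname} "
                f"({len(seq) // 3} codons)")
        ins = _random_cds(rng, aa_len + 2, 0.35, 0.6)[3:-3]  # stop-free codons
        cut = 3 * aa_start
        plan[i] = (name, cls, strand, seq[:cut] + ins + seq[cut:])
        truth.events["insert"] = {"gene": gname, "aa_start": aa_start + 1,
                                  "aa_end": aa_start + aa_len,
                                  "insert_nt": len(ins)}

    topology = genome.topology
    gc = 0.31
    new_genome, spacers = _assemble(plan, topology, gc, 58.0, rng,
                                    genome.id + "_evt")
    truth.spacer_lengths = spacers
    truth.gene_lengths = {n: len(s) for n, _, _, s in plan}
    return new_genome, truth


def simulate_trans_splice(cds: str, aa_cut: int, junction_insert: str = "AAAAA",
                          n_upstream_edits: int = 10, seed: int = 0
                          ) -> tuple[str, str, str, SimulationTruth]:
    """Split a CDS into two gene pieces and emit the trans-spliced transcript.

    The transcript is part1 + ``junction_insert`` + part2 with
    ``n_upstream_edits`` substitutional edits planted upstream of the
    junction (editing concentrates there in real transcripts). Returns
    (part1, part2, transcript, truth).
    """
    rng = stream(seed, "trans_splice")
    cds = cds.upper()
    cut_nt = 3 * aa_cut
    part1, part2 = cds[:cut_nt], cds[cut_nt:]
    edited = list(part1)
    positions = rng.choice(len(part1), size=min(n_upstream_edits, len(part1)),
                           replace=False)
    for pos in positions:
        alternatives = [b for b in "ACGT" if b != edited[pos]]
        edited[pos] = alternatives[rng.integers(3)]
    transcript = "".join(edited) + junction_insert + part2
    truth = SimulationTruth(seed=seed, events={
        "junction_aa": (aa_cut, aa_cut + 1),
        "insert": junction_insert,
        "upstream_edits": sorted(int(p) + 1 for p in positions),
    })
    return part1, part2, transcript, truth
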