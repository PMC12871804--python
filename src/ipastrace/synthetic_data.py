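"""Seeded generators for every input the pipeline consumes.

Each generator is a pure function of (seed, parameters): the same call is
byte-identical on regeneration, and every dataset carries a
:class:`SimulationTruth` sidecar recording the planted ground truth.
Parameter-recovery tests elsewhere read truth only from the sidecar.

A single global seed fans out to per-stage child seeds through
:func:`child_seed` (a ``numpy.random.SeedSequence`` keyed on a fixed stage
index), so individual stages are independently reproducible.

Defaults mirror the study system: a ten-exon gene whose fifth intron
carries a FLAM-like monomeric Alu element (~130 bp) whose A-rich tail
holds three partially overlapping AATAAA hexamers, placed so the predicted
cleavage site sits ~276 nt into the intron (a ~240 nt intron-derived
3'UTR); junction tables with four shared upstream and five
full-length-exclusive downstream junctions; IP-MS runs of three technical
replicates.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from ipastrace.intervals import DictGenome, GeneModel, GenomicInterval
from ipastrace.junction_usage import JunctionRecord
from ipastrace.longread_classify import ExonChain, IsoformModel
from ipastrace.pas_scan import CANONICAL_PAS, RepeatAnnotation
from ipastrace.pas_evolution import SpeciesTree, parse_newick
from ipastrace.interface_map import AtomSet

_STAGE_IDS = {
    "locus": 1,
    "junctions": 2,
    "tree": 3,
    "spectra": 4,
    "longreads": 5,
    "structure": 6,
}


def child_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage child seed derived from one global seed."""
    ss = np.random.SeedSequence([int(global_seed), _STAGE_IDS[stage]])
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


@dataclass
class SimulationTruth:
    """Ground truth planted by a generator, serializable alongside data."""

    seed: int
    stage: str
    params: dict = field(default_factory=dict)

    def to_json(self) -> str:
        def default(o):
            if isinstance(o, (np.integer,)):
                return int(o)
            if isinstance(o, (np.floating,)):
                return float(o)
            if isinstance(o, np.ndarray):
                return o.tolist()
            if dataclasses.is_dataclass(o):
                return dataclasses.asdict(o)
            return str(o)

        return json.dumps(dataclasses.asdict(self), indent=2, default=default)

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_json())


# ------------------------------------------------------------------- locus

# FLAM-like monomeric Alu body (~100 bp, free of AATAAA); the generator
# appends the A-rich tail that carries the planted signals.
_FLAM_BODY = (
    "GGCCGGGCGCGGTGGCTCACGCCTGTAATCCCAGCACTTTGGGAGGCCGAGGCGGGCGGA"
    "TCACGAGGTCAGGAGATCGAGACCATCCCGGCTAAAACGG"
)

_SAFE_CODONS = ("GCT", "GAA", "CTG", "AAG", "GTT", "TCC", "GAC", "CGT")


@dataclass
class LocusSim:
    """A synthetic gene locus with a planted repeat-borne PAS."""

    genome: DictGenome
    model: GeneModel
    repeats: list[RepeatAnnotation]
    truth: SimulationTruth

    @property
    def chrom_sequence(self) -> str:
        return self.genome.sequences[self.model.chrom]


def gen_locus(
    seed: int,
    n_exons: int = 10,
    exon_length: int = 120,
    intron_length: int = 800,
    pas_intron_index: int = 4,
    element_offset: int = 145,
    n_planted_pas: int = 3,
    tail_residues: int = 11,
    mutation_rate: float = 0.0,
    chrom: str = "chrS",
    flank: int = 200,
) -> LocusSim:
    """Generate a gene whose ``pas_intron_index``-th intron carries an
    Alu-like element with an A-rich tail holding exactly ``n_planted_pas``
    overlapping AATAAA hexamers.

    The intron also carries a short in-frame coding extension ending at a
    stop codon (``tail_residues`` codons), so the truncated-isoform ORF
    prediction has a planted answer.  The default element offset places the
    predicted cleavage site ~276 nt into the intron, yielding a ~240 nt
    intron-derived 3'UTR — the geometry of the locus that motivates these
    defaults.  Point mutations at ``mutation_rate``
    hit the element body but never the planted hexamers.  Any AATAAA
    arising by chance outside the planted run is destroyed, so a scan of
    the locus recovers exactly the planted signals.
    """
    if n_planted_pas < 0:
        raise ValueError("n_planted_pas must be >= 0")
    rng = np.random.default_rng(seed)

    if n_planted_pas > 0:
        pas_run = CANONICAL_PAS + "TAAA" * (n_planted_pas - 1)
    else:
        pas_run = "AAGAAAGAAA"  # A-rich but signal-free
    element = _FLAM_BODY + "GAAAG" + pas_run + "AAAA" * 4
    if mutation_rate > 0:
        element = _mutate_outside(
            rng, element, mutation_rate, start=len(_FLAM_BODY) + 5, length=len(pas_run)
        )
    if intron_length < element_offset + len(element) + 3 * tail_residues + 3 + 20:
        raise ValueError("intron too short for the planted element")

    # coding exons: ATG + safe codons (no stops, no AATAAA possible)
    n_codons = (n_exons * exon_length) // 3
    codons = ["ATG"] + list(rng.choice(_SAFE_CODONS, size=n_codons - 1))
    coding = "".join(codons)

    exon_seqs = [coding[i * exon_length : (i + 1) * exon_length] for i in range(n_exons)]

    def filler(n: int) -> str:
        return "".join(rng.choice(list("ACGT"), size=n, p=[0.25, 0.2, 0.3, 0.25]))

    tail_nt = "".join(rng.choice(_SAFE_CODONS, size=tail_residues)) + "TGA"
    intron_seqs = []
    for i in range(n_exons - 1):
        if i == pas_intron_index:
            pre = tail_nt + filler(element_offset - len(tail_nt))
            post = filler(intron_length - len(pre) - len(element))
            intron_seqs.append(pre + element + post)
        else:
            intron_seqs.append(filler(intron_length))

    parts, exon_ivs, pos = [], [], flank
    parts.append(filler(flank))
    intron_coords = []
    for i, es in enumerate(exon_seqs):
        exon_ivs.append(GenomicInterval(chrom, pos, pos + len(es), "+"))
        parts.append(es)
        pos += len(es)
        if i < n_exons - 1:
            intron_coords.append(pos)
            parts.append(intron_seqs[i])
            pos += len(intron_seqs[i])
    parts.append(filler(flank))
    seq = "".join(parts)

    pas_intron_start = intron_coords[pas_intron_index]
    element_start = pas_intron_start + element_offset
    planted_starts = []
    if n_planted_pas > 0:
        run_start = element_start + len(_FLAM_BODY) + 5
        planted_starts = [run_start + 4 * k for k in range(n_planted_pas)]

    # destroy accidental AATAAA outside the planted run
    protected = set()
    for s in planted_starts:
        protected.update(range(s, s + 6))
    seq = _destroy_motif(seq, CANONICAL_PAS, protected)

    genome = DictGenome({chrom: seq})
    model = GeneModel(
        gene_id="SIMGENE",
        strand="+",
        exons=exon_ivs,
        cds=list(exon_ivs),
        genome=genome,
    )
    repeats = [
        RepeatAnnotation(
            interval=GenomicInterval(chrom, element_start, element_start + len(element), "+"),
            repeat_name="FLAM-C",
            repeat_class="SINE/Alu",
        )
    ]
    expected_cleavage = (planted_starts[0] + 6 + 20) if planted_starts else None
    truth = SimulationTruth(
        seed=seed,
        stage="locus",
        params={
            "n_exons": n_exons,
            "exon_length": exon_length,
            "intron_length": intron_length,
            "pas_intron_index": pas_intron_index,
            "n_planted_pas": n_planted_pas,
            "planted_pas_starts": planted_starts,
            "element_interval": [element_start, element_start + len(element)],
            "expected_cleavage_site": expected_cleavage,
            "tail_residues": tail_residues,
            "mutation_rate": mutation_rate,
        },
    )
    return LocusSim(genome=genome, model=model, repeats=repeats, truth=truth)


def _mutate_outside(rng, seq: str, rate: float, start: int, length: int) -> str:
    chars = list(seq)
    for i in range(len(chars)):
        if start <= i < start + length:
            continue
        if rng.random() < rate:
            chars[i] = rng.choice([b for b in "ACGT" if b != chars[i]])
    return "".join(chars)


def _destroy_motif(seq: str, motif: str, protected: set[int]) -> str:
    chars = list(seq)
    changed = True
    while changed:
        changed = False
        s = "".join(chars)
        pos = s.find(motif)
        while pos != -1:
            span = set(range(pos, pos + len(motif)))
            if not span & protected:
                chars[pos + 2] = "C"  # break the motif centre
                changed = True
            pos = s.find(motif, pos + 1)
    return "".join(chars)


# --------------------------------------------------------------- junctions


@dataclass
class JunctionSim:
    up_counts: np.ndarray
    down_counts: np.ndarray
    records: list[JunctionRecord]
    truth: SimulationTruth


def gen_junction_counts(
    seed: int,
    psi: float,
    depth: int = 10_000,
    n_up: int = 4,
    n_down: int = 5,
    dispersion: float = 0.0,
    chrom: str = "chrS",
) -> JunctionSim:
    """Junction counts under a two-isoform mixture with short fraction psi.

    Upstream junctions (shared by both isoforms) have weight 1; downstream
    junctions (full-length only) weight 1 - psi.  Counts are multinomial at
    total ``depth``; ``dispersion`` > 0 adds extra-multinomial noise by
    drawing the probabilities from a Dirichlet with concentration
    weights/dispersion.
    """
    if not 0.0 <= psi <= 1.0:
        raise ValueError("psi must lie in [0, 1]")
    if depth <= 0:
        raise ValueError("depth must be positive")
    rng = np.random.default_rng(seed)
    weights = np.concatenate([np.ones(n_up), np.full(n_down, 1.0 - psi)])
    if weights.sum() == 0:
        raise ValueError("psi=1 with no upstream junctions leaves nothing to sample")
    p = weights / weights.sum()
    if dispersion > 0:
        p = rng.dirichlet(weights / dispersion)
    counts = rng.multinomial(depth, p)
    records = []
    for i, c in enumerate(counts):
        s = 1000 + 500 * i
        records.append(
            JunctionRecord(
                chrom=chrom,
                intron_start=s,
                intron_end=s + 400,
                strand="+",
                unique_reads=int(c),
            )
        )
    truth = SimulationTruth(
        seed=seed,
        stage="junctions",
        params={
            "psi": psi,
            "depth": depth,
            "n_up": n_up,
            "n_down": n_down,
            "dispersion": dispersion,
        },
    )
    return JunctionSim(
        up_counts=counts[:n_up].astype(float),
        down_counts=counts[n_up:].astype(float),
        records=records,
        truth=truth,
    )


def write_sj_table(path, records: list[JunctionRecord]) -> None:
    """Write junction records in the 9-column STAR SJ.out.tab dialect."""
    code = {".": 0, "+": 1, "-": 2}
    with open(path, "w") as fh:
        for r in records:
            fh.write(
                "\t".join(
                    map(
                        str,
                        [
                            r.chrom,
                            r.intron_start + 1,
                            r.intron_end,
                            code[r.strand],
                            0,
                            1,
                            r.unique_reads,
                            r.multi_reads,
                            30,
                        ],
                    )
                )
                + "\n"
            )


# -------------------------------------------------------------------- tree


@dataclass
class TreeCharacterSim:
    characters: dict[str, tuple[str, int | None]]
    truth: SimulationTruth


def gen_tree_characters(
    seed: int,
    stree: SpeciesTree,
    gain_rate: float = 0.0,
    loss_rate: float = 0.0,
    insertion_clade: tuple[str, ...] | None = None,
    root_count: int = 1,
    planted_count_events: dict[tuple[str, ...], int] | None = None,
) -> TreeCharacterSim:
    """Simulate element presence and PAS count down a species tree.

    A single insertion is placed on one branch (chosen uniformly unless
    ``insertion_clade`` pins it); below it, each branch loses the element
    with probability ``loss_rate`` and changes the count by +/-1 with
    probability ``gain_rate`` (floored at 0).  ``planted_count_events`` maps
    clade -> delta for deterministic histories.  Truth records every event
    branch.
    """
    if gain_rate < 0 or loss_rate < 0:
        raise ValueError("rates must be >= 0")
    rng = np.random.default_rng(seed)
    tree = stree.tree
    nodes = [n for n in tree.preorder_node_iter() if n.parent_node is not None]
    if insertion_clade is not None:
        target = tuple(sorted(insertion_clade))
        ins_node = next(
            n for n in tree.preorder_node_iter() if n.clade == target
        )  # the root clade pins the insertion above the root
    else:
        ins_node = nodes[rng.integers(len(nodes))]

    presence: dict[str, bool] = {}
    counts: dict[str, int | None] = {}
    losses: list[tuple[str, ...]] = []
    count_events: list[dict] = []
    planted = {tuple(sorted(k)): v for k, v in (planted_count_events or {}).items()}

    def walk(node, present: bool, count: int) -> None:
        if node.parent_node is not None and present:
            if node is not ins_node and rng.random() < loss_rate:
                present = False
                losses.append(node.clade)
            elif node.clade in planted:
                delta = planted[node.clade]
                count = max(0, count + delta)
                count_events.append({"branch": node.clade, "delta": delta})
            elif rng.random() < gain_rate:
                delta = int(rng.choice([-1, 1])) if count > 0 else 1
                count = max(0, count + delta)
                count_events.append({"branch": node.clade, "delta": delta})
        if node.is_leaf():
            lbl = node.taxon.label
            presence[lbl] = present
            counts[lbl] = count if present else None
            return
        for ch in node.child_nodes():
            walk(ch, present, count)

    # above the insertion branch: absent
    def walk_above(node) -> None:
        if node is ins_node:
            walk(node, True, root_count)
            return
        if node.is_leaf():
            presence[node.taxon.label] = False
            counts[node.taxon.label] = None
            return
        for ch in node.child_nodes():
            walk_above(ch)

    walk_above(tree.seed_node)
    characters = {
        tip: ("present" if presence[tip] else "absent", counts[tip])
        for tip in stree.tip_labels
    }
    truth = SimulationTruth(
        seed=seed,
        stage="tree",
        params={
            "insertion_branch": list(ins_node.clade),
            "loss_branches": [list(b) for b in losses],
            "count_events": [
                {"branch": list(e["branch"]), "delta": e["delta"]} for e in count_events
            ],
            "root_count": root_count,
            "gain_rate": gain_rate,
            "loss_rate": loss_rate,
        },
    )
    return TreeCharacterSim(characters=characters, truth=truth)


# ------------------------------------------------------------------ spectra


@dataclass
class SpectraSim:
    counts: pd.DataFrame
    lengths: pd.Series
    truth: SimulationTruth


def gen_spectral_counts(
    seed: int,
    stoichiometry: dict[str, float],
    lengths: dict[str, int],
    n_background: int = 50,
    background_abundance: float = 0.02,
    depth: int = 5000,
    n_runs: int = 3,
) -> SpectraSim:
    """Spectral counts multinomially proportional to abundance x length.

    Complex members follow the given molar ``stoichiometry``; background
    proteins get low abundance and random lengths, emulating the
    non-specific binders of an IP.  One multinomial of size ``depth`` per
    run (technical replicates).
    """
    if any(v <= 0 for v in stoichiometry.values()):
        raise ValueError("stoichiometry values must be positive")
    if depth <= 0:
        raise ValueError("depth must be positive")
    rng = np.random.default_rng(seed)
    names = list(stoichiometry)
    abund = [stoichiometry[n] for n in names]
    lens = [lengths[n] for n in names]
    for i in range(n_background):
        names.append(f"BG{i + 1:03d}")
        abund.append(background_abundance)
        lens.append(int(rng.integers(100, 1000)))
    abund = np.asarray(abund, dtype=float)
    lens_arr = np.asarray(lens, dtype=float)
    p = abund * lens_arr
    p = p / p.sum()
    runs = {
        f"run{r + 1}": rng.multinomial(depth, p) for r in range(n_runs)
    }
    counts = pd.DataFrame(runs, index=names)
    truth = SimulationTruth(
        seed=seed,
        stage="spectra",
        params={
            "stoichiometry": dict(stoichiometry),
            "depth": depth,
            "n_runs": n_runs,
            "n_background": n_background,
            "background_abundance": background_abundance,
        },
    )
    return SpectraSim(counts=counts, lengths=pd.Series(lens, index=names), truth=truth)


# ---------------------------------------------------------------- longreads


@dataclass
class LongReadSim:
    reads: list[ExonChain]
    labels: list[str]
    truth: SimulationTruth


def gen_longreads(
    seed: int,
    models: list[IsoformModel],
    n_reads_per_model: int = 20,
    end_jitter_sd: float = 10.0,
    junction_noise_rate: float = 0.0,
) -> LongReadSim:
    """Sample reads from isoform models with terminal jitter and optional
    junction corruption (a corrupted junction is shifted by 10-30 nt, which
    breaks exact junction matching by construction)."""
    rng = np.random.default_rng(seed)
    reads, labels, corrupted = [], [], []
    for m in models:
        for k in range(n_reads_per_model):
            exons = [list(e) for e in m.chain.exons]
            j5 = int(round(rng.normal(0, end_jitter_sd)))
            j3 = int(round(rng.normal(0, end_jitter_sd)))
            exons[0][0] = min(exons[0][0] + j5, exons[0][1] - 1)
            exons[-1][1] = max(exons[-1][1] + j3, exons[-1][0] + 1)
            was_corrupted = False
            if junction_noise_rate > 0 and len(exons) > 1:
                if rng.random() < junction_noise_rate:
                    ji = int(rng.integers(len(exons) - 1))
                    shift = int(rng.integers(10, 31)) * int(rng.choice([-1, 1]))
                    new_end = exons[ji][1] + shift
                    if exons[ji][0] < new_end < exons[ji + 1][0]:
                        exons[ji][1] = new_end
                        was_corrupted = True
            reads.append(
                ExonChain(
                    chrom=m.chain.chrom,
                    strand=m.chain.strand,
                    exons=[tuple(e) for e in exons],
                    name=f"{m.name}_read{k}",
                )
            )
            labels.append(m.name)
            corrupted.append(was_corrupted)
    truth = SimulationTruth(
        seed=seed,
        stage="longreads",
        params={
            "labels": labels,
            "corrupted": corrupted,
            "end_jitter_sd": end_jitter_sd,
            "junction_noise_rate": junction_noise_rate,
        },
    )
    return LongReadSim(reads=reads, labels=labels, truth=truth)


# ---------------------------------------------------------------- structure


@dataclass
class StructureSim:
    atoms: AtomSet
    truth: SimulationTruth


def gen_toy_structure(seed: int, geometry: dict, probe_radius: float = 1.4) -> StructureSim:
    """Toy atomic clusters with analytically known accessible/buried areas.

    Geometries: ``single_sphere`` (radius r), ``two_spheres`` (radius r,
    centre distance d), ``shell`` (one target atom enclosed by a dense
    partner-atom shell).  Truth records the closed-form values where they
    exist: an isolated sphere exposes 4*pi*(r+probe)^2; two equal spheres at
    distance d < 2(r+probe) each bury a spherical cap of area
    2*pi*R*(R - d/2) with R = r + probe.
    """
    kind = geometry.get("kind")
    rng = np.random.default_rng(seed)
    if kind == "single_sphere":
        r = float(geometry.get("radius", 1.7))
        atoms = AtomSet(
            coords=np.zeros((1, 3)),
            radii=np.array([r]),
            chains=np.array(["A"]),
            residues=np.array([1]),
            elements=np.array(["C"]),
        )
        R = r + probe_radius
        truth_params = {"geometry": geometry, "analytic_sasa": 4 * np.pi * R * R}
    elif kind == "two_spheres":
        r = float(geometry.get("radius", 1.7))
        d = float(geometry.get("distance", 2.0))
        if d <= 0:
            raise ValueError("two spheres may not share a centre")
        atoms = AtomSet(
            coords=np.array([[0.0, 0.0, 0.0], [d, 0.0, 0.0]]),
            radii=np.array([r, r]),
            chains=np.array(["A", "B"]),
            residues=np.array([1, 1]),
            elements=np.array(["C", "C"]),
        )
        R = r + probe_radius
        cap = 2 * np.pi * R * max(0.0, R - d / 2) if d < 2 * R else 0.0
        truth_params = {
            "geometry": geometry,
            "analytic_sasa_per_atom": 4 * np.pi * R * R - cap,
            "analytic_buried_per_atom": cap,
        }
    elif kind == "shell":
        r = float(geometry.get("radius", 1.7))
        shell_radius = float(geometry.get("shell_radius", 4.0))
        n_shell = int(geometry.get("n_shell", 200))
        from ipastrace.interface_map import golden_spiral_points

        pts = golden_spiral_points(n_shell) * shell_radius
        coords = np.vstack([np.zeros((1, 3)), pts])
        atoms = AtomSet(
            coords=coords,
            radii=np.full(len(coords), r),
            chains=np.array(["A"] + ["B"] * n_shell),
            residues=np.array([1] + [i + 1 for i in range(n_shell)]),
            elements=np.array(["C"] * len(coords)),
        )
        truth_params = {"geometry": geometry, "buried_fraction_lower_bound": 0.95}
    else:
        raise ValueError(f"unknown toy geometry {kind!r}")
    truth = SimulationTruth(seed=seed, stage="structure", params=truth_params)
    return StructureSim(atoms=atoms, truth=truth)


def write_pdb(path, atoms: AtomSet) -> None:
    """Write an AtomSet as a minimal PDB file (CA pseudo-atoms)."""
    with open(path, "w") as fh:
        for i in range(len(atoms)):
            x, y, z = atoms.coords[i]
            fh.write(
                f"ATOM  {i + 1:5d}  CA  GLY {str(atoms.chains[i])[:1]}"
                f"{int(atoms.residues[i]):4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          "
                f"{str(atoms.elements[i]):>2s}\n"
            )
        fh.write("END\n")


# ------------------------------------------------------------- fixture set


def load_primate_tree() -> SpeciesTree:
    """The bundled dated primate species tree (13 tips, ages in Mya from
    standard divergence-time estimates; the Neanderthal tip at ~0.05 Mya)."""
    text = (
        resources.files("ipastrace").joinpath("data/primate_tree.nwk").read_text()
    )
    return parse_newick(text, ultrametric=True)


def load_primate_characters() -> dict[str, tuple[str, int | None]]:
    """Per-species element presence and overlapping-AATAAA counts at the
    orthologous intronic site (curated from comparative genome alignments);
    'lost' marks absence with documented deletion breakpoints."""
    text = (
        resources.files("ipastrace")
        .joinpath("data/primate_pas_characters.tsv")
        .read_text()
    )
    chars: dict[str, tuple[str, int | None]] = {}
    for line in text.splitlines():
        if not line.strip() or line.startswith("tip"):
            continue
        tip, presence, count = line.split("\t")
        chars[tip] = (presence, None if count == "NA" else int(count))
    return chars
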