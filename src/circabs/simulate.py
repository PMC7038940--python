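"""Synthetic multi-tissue back-splice junction data with planted ground truth.

The generator emits everything the pipeline consumes — gene models, Alu
annotations, per-sample junction tables, a sample sheet, and optionally
genome sequence — together with the planted truth, so every stage has a
closed-loop test.

Model
-----
Each circRNA-producing locus is one synthetic gene.  A locus is either
constitutive (one circRNA) or part of an alternative back-splicing group:
an A5BS event (k members sharing the acceptor), an A3BS event (k members
sharing the donor), or a dual structure in which one circRNA participates
in both an A5BS and an A3BS event.  Back-splice sites always sit on exon
boundaries.

Locus activity is log-normal.  Member weights come from a Dirichlet with
one inflated component, creating a clear predominant circRNA; constitutive
circRNAs draw a random component of the same construction so that
abundance is independent of ABS status (what makes the saturation
asymptote equal the planted ABS fraction).  Per-tissue weight jitter (with
a coherent "brain-like" tissue block), per-individual noise, and Poisson
read sampling at the sample's mapped-read depth complete the model;
detection censoring arises naturally from Poisson sampling plus the
0.1 RPM high-confidence filter — low-abundance partners are missed, which
produces the coverage-dependent observed ABS fraction.

Tissue-specific events have their predominant weight shifted down by a
configured number of PCU points in designated tissues.  Feature effects
are planted in the annotation: longer/Alu-richer shared flanking introns
for high-complexity events, and longer/Alu-richer member-specific introns
for predominant members (strong on the A5BS side, weak on the A3BS side).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
import numpy as np
import pandas as pd

from . import events as ev
from .io import GeneModel, write_genepred, write_repeats_bed

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass
class SimConfig:
    """Generator settings; the defaults define the reference study conditions.

    Sizes are desk scale: 5,000 circRNA loci across 8 tissues with 2
    replicates at 20M mapped reads per sample.  ``abs_fraction`` is the
    planted fraction of circRNAs involved in ABS at saturation;
    ``pcu_shift`` is in PCU percentage points.
    """

    # --- locus plan
    n_loci: int = 5000
    abs_fraction: float = 0.84
    complexity_p: float = 0.6  # truncated geometric on complexity >= 2
    complexity_max: int = 10
    a5bs_share: float = 65.0 / (65.0 + 52.2)  # A5BS vs A3BS among single-type events
    dual_fraction: float = 0.2  # ABS groups coupling an A5BS and an A3BS event

    # --- abundance (RPM scale)
    abundance_mu: float = math.log(0.25)  # ln of locus activity median
    abundance_sigma: float = 1.6
    tissue_abundance_sigma: float = 0.7
    brain_abundance_boost: float = 1.5

    # --- PCU structure
    dirichlet_major: float = 6.0
    dirichlet_minor: float = 1.5
    pcu_tissue_sigma: float = 0.25  # log-weight jitter shared by individuals
    pcu_individual_sigma: float = 0.1
    block_coherence: float = 0.8  # shared fraction of brain-block tissue effects
    tissue_specific_fraction: float = 0.3
    pcu_shift: float = 40.0  # percentage points
    n_shift_tissues: int = 2

    # --- cohort
    tissues: tuple[str, ...] = (
        "frontal_cortex", "occipital_lobe", "cerebellum",
        "heart", "lung", "liver", "muscle", "kidney",
    )
    brain_tissues: tuple[str, ...] = ("frontal_cortex", "occipital_lobe", "cerebellum")
    individuals: int = 1
    replicates: int = 2
    depth: float = 20e6  # mapped reads per sample
    cohort: str = "fetal"

    # --- annotation geometry
    exon_len_range: tuple[int, int] = (100, 300)
    intron_mu: float = math.log(1200.0)
    intron_sigma: float = 0.8
    min_intron: int = 80
    alu_per_kb: float = 0.6
    alu_len_range: tuple[int, int] = (280, 320)
    alu_plus_prob: float = 0.5
    gene_gap: int = 2000
    chrom_size_limit: int = 30_000_000

    # --- planted feature effects (multipliers on intron length / Alu density)
    len_mult_low: float = 1.6
    len_mult_high: float = 2.5
    alu_mult_low: float = 1.6
    alu_mult_high: float = 2.5
    pred_len_mult_a5bs: float = 2.0
    pred_alu_mult_a5bs: float = 2.0
    pred_len_mult_a3bs: float = 1.5
    pred_alu_mult_a3bs: float = 1.0

    # --- sequence emission (CSI tests; small genomes only)
    emit_fasta: bool = False
    fasta_size_limit: int = 5_000_000
    alu_background_divergence: float = 0.25
    planted_pair_divergence: tuple[float, float] = (0.02, 0.2)  # predominant, other

    seed: int = 0


@dataclass
class _Group:
    """Internal plan for one gene/locus group (not part of the public API)."""

    gene_id: str
    kind: str  # a5bs | a3bs | dual | constitutive
    spans: list[tuple[int, int]]  # member exon spans, gene orientation, 1-based incl.
    events: list[tuple[str, list[int]]]  # (etype, member indices)
    predominant: int  # member index
    n_exons: int
    strand: str = "+"
    chrom: str = ""
    exons: tuple = ()  # genomic exon intervals
    keys: list[tuple] = field(default_factory=list)  # member circRNA keys
    tissue_specific: bool = False
    shift_tissues: tuple[int, ...] = ()


@dataclass
class Annotation:
    genes: list[GeneModel]
    repeats: pd.DataFrame  # chrom, start, end, strand, family, divergence
    plan: list[_Group]
    sequences: dict[str, str] | None = None


@dataclass
class SimTruth:
    """Planted ground truth emitted alongside the synthetic data."""

    alpha_true: float  # realized ABS fraction among all circRNA loci
    circ: pd.DataFrame  # index: circRNA key; name, gene_id, label, base_rpm
    events: pd.DataFrame  # index: event_id; etype, complexity, predominant...
    pcu: pd.DataFrame  # true per-tissue PCU (percent), event x tissue


@dataclass
class Simulation:
    config: SimConfig
    annotation: Annotation
    junctions: pd.DataFrame  # long: chrom strand start end name read_count sample_id
    sample_sheet: pd.DataFrame
    truth: SimTruth
    true_rpm: pd.DataFrame  # expected RPM per circRNA x sample (pre-Poisson)


# ---------------------------------------------------------------------------
# locus plan


def _draw_complexity(rng: np.random.Generator, cfg: SimConfig) -> int:
    ks = np.arange(2, cfg.complexity_max + 1)
    probs = (1.0 - cfg.complexity_p) ** (ks - 2)
    probs /= probs.sum()
    return int(rng.choice(ks, p=probs))


def _plan_loci(rng: np.random.Generator, cfg: SimConfig) -> list[_Group]:
    budget = int(round(cfg.abs_fraction * cfg.n_loci))
    groups: list[_Group] = []
    used = 0
    gid = 0

    def new_id():
        nonlocal gid
        gid += 1
        return f"geneS{gid:05d}"

    while budget - used >= 2:
        remaining = budget - used
        if remaining >= 3 and rng.random() < cfg.dual_fraction:
            # dual: c=(2,4) in both events, a=(2,3) A5BS partner, b=(3,4) A3BS partner
            groups.append(
                _Group(
                    gene_id=new_id(), kind="dual",
                    spans=[(2, 4), (2, 3), (3, 4)],
                    events=[(ev.A5BS, [0, 1]), (ev.A3BS, [0, 2])],
                    predominant=0, n_exons=6,
                )
            )
            used += 3
            continue
        k = min(_draw_complexity(rng, cfg), remaining)
        if rng.random() < cfg.a5bs_share:
            spans = [(2, 2 + j) for j in range(k)]
            etype = ev.A5BS
        else:
            spans = [(2 + j, k + 2) for j in range(k)][::-1]  # acceptors 2..k+1
            etype = ev.A3BS
        groups.append(
            _Group(
                gene_id=new_id(), kind=etype.lower(),
                spans=spans, events=[(etype, list(range(k)))],
                predominant=int(rng.integers(k)), n_exons=k + 4,
            )
        )
        used += k
    for _ in range(cfg.n_loci - used):
        groups.append(
            _Group(
                gene_id=new_id(), kind="constitutive",
                spans=[(2, 3)], events=[], predominant=0, n_exons=4,
            )
        )
    return groups


def _intron_multipliers(g: _Group, cfg: SimConfig) -> tuple[np.ndarray, np.ndarray]:
    """Per-intron (length, Alu-density) multipliers for one gene."""
    n_introns = g.n_exons - 1
    len_m = np.ones(n_introns)
    alu_m = np.ones(n_introns)
    if g.kind in ("a5bs", "a3bs"):
        k = len(g.spans)
        cls_len = cfg.len_mult_high if k >= 3 else cfg.len_mult_low
        cls_alu = cfg.alu_mult_high if k >= 3 else cfg.alu_mult_low
        if g.kind == "a5bs":
            shared = 1  # upstream intron of every member
            pred_intron = g.spans[g.predominant][1]  # predominant's downstream intron
            p_len, p_alu = cfg.pred_len_mult_a5bs, cfg.pred_alu_mult_a5bs
        else:
            shared = g.spans[0][1]  # downstream intron (k + 2)
            pred_intron = g.spans[g.predominant][0] - 1  # predominant's upstream intron
            p_len, p_alu = cfg.pred_len_mult_a3bs, cfg.pred_alu_mult_a3bs
        len_m[shared - 1] *= cls_len
        alu_m[shared - 1] *= cls_alu
        len_m[pred_intron - 1] *= p_len
        alu_m[pred_intron - 1] *= p_alu
    elif g.kind == "dual":
        len_m[0] *= cfg.len_mult_low
        alu_m[0] *= cfg.alu_mult_low
        len_m[3] *= cfg.len_mult_low
        alu_m[3] *= cfg.alu_mult_low
    return len_m, alu_m


# ---------------------------------------------------------------------------
# annotation


def simulate_annotation(config: SimConfig) -> Annotation:
    """Build gene models and Alu repeats for the planned loci.

    Genes are packed sequentially (gap ``gene_gap``) onto synthetic
    chromosomes capped at ``chrom_size_limit``; strands alternate randomly.
    Intron lengths are log-normal with the planted multipliers applied;
    Alus are placed Poisson per kb of intron with the configured
    orientation probability, plus one planted inverted pair per ABS member
    when sequences are emitted.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0]))
    groups = _plan_loci(rng, config)
    # tissue-specific flags belong to the junction model but are part of the
    # deterministic plan, drawn here so the annotation and junction steps agree
    tissue_idx = np.arange(len(config.tissues))
    for g in groups:
        if g.kind != "constitutive" and rng.random() < config.tissue_specific_fraction:
            g.tissue_specific = config.pcu_shift > 0
            picked = rng.choice(tissue_idx, size=min(config.n_shift_tissues, len(tissue_idx)), replace=False)
            g.shift_tissues = tuple(int(t) for t in sorted(picked))

    genes: list[GeneModel] = []
    repeat_rows: list[tuple] = []
    chrom_no, cursor = 1, 0
    lo, hi = config.exon_len_range

    for g in groups:
        strand = "+" if rng.random() < 0.5 else "-"
        exon_lens = rng.integers(lo, hi + 1, size=g.n_exons)
        len_m, alu_m = _intron_multipliers(g, config)
        intron_lens = np.maximum(
            config.min_intron,
            (rng.lognormal(config.intron_mu, config.intron_sigma, size=g.n_exons - 1) * len_m).astype(int),
        )
        # genomic order: gene order on "+", reversed on "-"
        ex_g = exon_lens if strand == "+" else exon_lens[::-1]
        in_g = intron_lens if strand == "+" else intron_lens[::-1]
        span = int(ex_g.sum() + in_g.sum())
        if span + config.gene_gap > config.chrom_size_limit:
            raise ValueError(
                "gene span exceeds chrom_size_limit; increase the limit or shrink introns"
            )
        if cursor + span + config.gene_gap > config.chrom_size_limit:
            chrom_no += 1
            cursor = 0
        chrom = f"chrS{chrom_no}"
        exons = []
        pos = cursor + config.gene_gap // 2
        for i, el in enumerate(ex_g):
            exons.append((pos, pos + int(el)))
            pos += int(el)
            if i < len(in_g):
                pos += int(in_g[i])
        cursor += span + config.gene_gap
        g.chrom, g.strand, g.exons = chrom, strand, tuple(exons)
        genes.append(GeneModel(g.gene_id, chrom, strand, tuple(exons)))

        def genomic_exon(idx: int) -> int:  # 1-based gene-order index -> 0-based genomic
            return idx - 1 if strand == "+" else g.n_exons - idx

        g.keys = []
        for a, b in g.spans:
            ga, gb = sorted((genomic_exon(a), genomic_exon(b)))
            g.keys.append((chrom, strand, exons[ga][0], exons[gb][1]))

        # background Alus, Poisson per kb of intron
        alu_lo, alu_hi = config.alu_len_range
        introns_genomic = [(exons[i][1], exons[i + 1][0]) for i in range(g.n_exons - 1)]
        dens_g = alu_m if strand == "+" else alu_m[::-1]
        for (istart, iend), dens in zip(introns_genomic, dens_g):
            ilen = iend - istart
            n = rng.poisson(config.alu_per_kb * dens * ilen / 1000.0)
            for _ in range(n):
                alen = int(rng.integers(alu_lo, alu_hi + 1))
                if ilen <= alen + 2:
                    continue
                s = istart + 1 + int(rng.integers(ilen - alen - 1))
                alu_strand = "+" if rng.random() < config.alu_plus_prob else "-"
                repeat_rows.append(
                    (chrom, s, s + alen, alu_strand, "AluY",
                     config.alu_background_divergence, -1)
                )

        if config.emit_fasta and g.kind in ("a5bs", "a3bs"):
            # one planted inverted pair per member across its two flanking
            # introns; the two copies share a motif, background Alus do not
            for mi, (a, b) in enumerate(g.spans):
                up_idx, down_idx = a - 1, b  # gene-order intron indices
                div = config.planted_pair_divergence[0 if mi == g.predominant else 1]
                pair_id = len(repeat_rows)  # unique, deterministic
                for intron_idx, alu_strand in ((up_idx, "+"), (down_idx, "-")):
                    gi = intron_idx - 1 if strand == "+" else g.n_exons - 1 - intron_idx
                    istart, iend = introns_genomic[gi]
                    alen = int(rng.integers(alu_lo, alu_hi + 1))
                    if iend - istart <= alen + 2:
                        continue
                    s = istart + 1 + int(rng.integers(iend - istart - alen - 1))
                    repeat_rows.append((chrom, s, s + alen, alu_strand, "AluY", div, pair_id))

    repeats = pd.DataFrame(
        repeat_rows,
        columns=["chrom", "start", "end", "strand", "family", "divergence", "pair_id"],
    ).sort_values(["chrom", "start", "end"], kind="mergesort", ignore_index=True)

    sequences = _emit_sequences(rng, config, genes, repeats) if config.emit_fasta else None
    return Annotation(genes=genes, repeats=repeats, plan=groups, sequences=sequences)


def _mutate(seq: np.ndarray, divergence: float, rng: np.random.Generator) -> np.ndarray:
    out = seq.copy()
    hit = rng.random(len(seq)) < divergence
    out[hit] = _BASES[rng.integers(0, 4, size=int(hit.sum()))]
    return out


_COMP = {b"A": b"T", b"C": b"G", b"G": b"C", b"T": b"A"}


def _revcomp(arr: np.ndarray) -> np.ndarray:
    comp = arr.copy()
    for a, b in _COMP.items():
        comp[arr == np.frombuffer(a, dtype="S1")[0]] = np.frombuffer(b, dtype="S1")[0]
    return comp[::-1]


def _emit_sequences(rng, config: SimConfig, genes, repeats) -> dict[str, str]:
    sizes: dict[str, int] = {}
    for g in genes:
        sizes[g.chrom] = max(sizes.get(g.chrom, 0), g.tx_end + config.gene_gap)
    total = sum(sizes.values())
    if total > config.fasta_size_limit:
        raise ValueError(
            f"genome of {total} bp exceeds fasta_size_limit; reduce n_loci for sequence emission"
        )
    chrom_seq = {c: _BASES[rng.integers(0, 4, size=n)] for c, n in sizes.items()}
    motif_len = max(config.alu_len_range)
    motifs: dict[int, np.ndarray] = {}
    for r in repeats.itertuples(index=False):
        if r.pair_id < 0:
            continue  # background Alus keep the random chromosome sequence
        if r.pair_id not in motifs:
            motifs[r.pair_id] = _BASES[rng.integers(0, 4, size=motif_len)]
        inst = _mutate(motifs[r.pair_id][: r.end - r.start], r.divergence, rng)
        if r.strand == "-":
            inst = _revcomp(inst)
        chrom_seq[r.chrom][r.start : r.end] = inst
    return {c: s.tobytes().decode() for c, s in chrom_seq.items()}


# ---------------------------------------------------------------------------
# junction tables


def _truth_label(g: _Group, mi: int) -> str:
    if g.kind == "constitutive":
        return ev.CONSTITUTIVE
    if g.kind == "dual":
        return (ev.BOTH, ev.A5BS, ev.A3BS)[mi]
    return ev.A5BS if g.kind == "a5bs" else ev.A3BS


def simulate_junctions(config: SimConfig, annotation: Annotation) -> Simulation:
    """Sample per-sample junction tables from the planned loci.

    See the module docstring for the generative model.  Outputs are
    byte-deterministic for a given config.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    groups = annotation.plan
    tissues = list(config.tissues)
    n_t = len(tissues)
    brain = np.array([t in config.brain_tissues for t in tissues])

    keys, names, gene_ids, labels, grp_idx, member_idx = [], [], [], [], [], []
    for gi, g in enumerate(groups):
        for mi, key in enumerate(g.keys):
            keys.append(key)
            names.append(f"circ{len(keys):05d}")
            gene_ids.append(g.gene_id)
            labels.append(_truth_label(g, mi))
            grp_idx.append(gi)
            member_idx.append(mi)
    n_circ = len(keys)
    grp_idx = np.array(grp_idx)

    # locus activity and base member weights
    activity = rng.lognormal(config.abundance_mu, config.abundance_sigma, size=len(groups))
    w_base = np.empty(n_circ)
    for gi, g in enumerate(groups):
        m = len(g.spans)
        if g.kind == "constitutive":
            k = _draw_complexity(rng, config)
            conc = np.full(k, config.dirichlet_minor)
            conc[0] = config.dirichlet_major
            w = rng.dirichlet(conc)
            w_base[grp_idx == gi] = w[int(rng.integers(k))]
        else:
            conc = np.full(m, config.dirichlet_minor)
            conc[g.predominant] = config.dirichlet_major
            w = rng.dirichlet(conc)
            # keep the planned predominant the realized maximum so that
            # planted annotation features and the truth tables agree
            top = int(np.argmax(w))
            w[g.predominant], w[top] = w[top], w[g.predominant]
            w_base[grp_idx == gi] = w

    # per-tissue abundance factor at the group level (members co-regulated)
    a_gt = np.exp(rng.normal(0.0, config.tissue_abundance_sigma, size=(len(groups), n_t)))
    a_gt[:, brain] *= config.brain_abundance_boost

    # per-tissue weight jitter; brain-block tissues share most of their effect
    z = rng.standard_normal((n_circ, n_t))
    z_block = rng.standard_normal(n_circ)
    coh = config.block_coherence
    z[:, brain] = math.sqrt(coh) * z_block[:, None] + math.sqrt(1 - coh) * z[:, brain]
    w_ct = w_base[:, None] * np.exp(config.pcu_tissue_sigma * z)

    # planted tissue-specific PCU shifts
    for gi, g in enumerate(groups):
        if not g.tissue_specific:
            continue
        rows = np.flatnonzero(grp_idx == gi)
        pred_row = rows[g.predominant]
        for t in g.shift_tissues:
            total = w_ct[rows, t].sum()
            p = w_ct[pred_row, t] / total
            p_new = float(np.clip(p - config.pcu_shift / 100.0, 0.02, 0.98))
            others = rows[rows != pred_row]
            scale = (total - p_new * total) / w_ct[others, t].sum()
            w_ct[others, t] *= scale
            w_ct[pred_row, t] = p_new * total

    rpm_ct = activity[grp_idx, None] * a_gt[grp_idx, :] * w_ct

    # samples: individual noise then Poisson reads at depth
    sample_ids, sample_meta, rpm_cols = [], [], []
    ind_factor = np.exp(
        rng.normal(0.0, config.pcu_individual_sigma, size=(n_circ, config.individuals))
    )
    for t_i, tissue in enumerate(tissues):
        for ind in range(config.individuals):
            for rep in range(config.replicates):
                sid = f"{tissue}.ind{ind + 1}.r{rep + 1}"
                sample_ids.append(sid)
                sample_meta.append(
                    {
                        "sample_id": sid,
                        "tissue": tissue,
                        "individual": f"ind{ind + 1}",
                        "cohort": config.cohort,
                        "replicate": rep + 1,
                        "mapped_reads": int(config.depth),
                        "tissue_group": "brain" if brain[t_i] else "non-brain",
                    }
                )
                rpm_cols.append(rpm_ct[:, t_i] * ind_factor[:, ind])
    true_rpm = np.column_stack(rpm_cols)
    reads = rng.poisson(true_rpm * (config.depth / 1e6))

    key_index = pd.MultiIndex.from_tuples(keys, names=["chrom", "strand", "start", "end"])
    rows = []
    for s_i, sid in enumerate(sample_ids):
        nz = np.flatnonzero(reads[:, s_i])
        for ci in nz:
            chrom, strand, start, end = keys[ci]
            rows.append((chrom, strand, start, end, names[ci], int(reads[ci, s_i]), sid))
    junctions = pd.DataFrame(
        rows, columns=["chrom", "strand", "start", "end", "name", "read_count", "sample_id"]
    )
    sheet = pd.DataFrame(sample_meta).set_index("sample_id")

    truth = _build_truth(config, groups, keys, names, gene_ids, labels, grp_idx, w_base, w_ct, rpm_ct, key_index, tissues)
    return Simulation(
        config=config,
        annotation=annotation,
        junctions=junctions,
        sample_sheet=sheet,
        truth=truth,
        true_rpm=pd.DataFrame(true_rpm, index=key_index, columns=sample_ids),
    )


def _build_truth(config, groups, keys, names, gene_ids, labels, grp_idx, w_base, w_ct, rpm_ct, key_index, tissues) -> SimTruth:
    circ = pd.DataFrame(
        {
            "name": names,
            "gene_id": gene_ids,
            "label": labels,
            "base_rpm": rpm_ct.mean(axis=1),
        },
        index=key_index,
    )
    ev_rows, pcu_rows = [], {}
    for gi, g in enumerate(groups):
        rows = np.flatnonzero(grp_idx == gi)
        for etype, member_ids in g.events:
            m_rows = rows[member_ids]
            w_members = w_base[m_rows]
            pred_local = int(np.argmax(w_members))
            pred_row = m_rows[pred_local]
            key0 = keys[m_rows[0]]
            chrom, strand, start, end = keys[pred_row]
            # shared site coordinate defines the deterministic event id
            from .io import acceptor_pos, donor_pos

            if etype == ev.A5BS:
                site = acceptor_pos(key0[1], key0[2], key0[3])
            else:
                site = donor_pos(key0[1], key0[2], key0[3])
            event_id = f"{etype}:{key0[0]}:{key0[1]}:{site}"
            ev_rows.append(
                {
                    "event_id": event_id,
                    "etype": etype,
                    "complexity": len(member_ids),
                    "gene_id": g.gene_id,
                    "predominant_name": names[pred_row],
                    "predominant_key": keys[pred_row],
                    "tissue_specific": g.tissue_specific,
                    "shift_tissues": ";".join(tissues[t] for t in g.shift_tissues),
                }
            )
            totals = w_ct[m_rows, :].sum(axis=0)
            pcu_rows[event_id] = 100.0 * w_ct[pred_row, :] / totals
    events_df = pd.DataFrame(ev_rows).set_index("event_id") if ev_rows else pd.DataFrame(
        columns=["etype", "complexity", "gene_id", "predominant_name",
                 "predominant_key", "tissue_specific", "shift_tissues"]
    )
    pcu_df = pd.DataFrame.from_dict(pcu_rows, orient="index", columns=list(tissues))
    pcu_df.index.name = "event_id"
    n_abs = int((circ["label"] != ev.CONSTITUTIVE).sum())
    return SimTruth(
        alpha_true=n_abs / len(circ),
        circ=circ,
        events=events_df,
        pcu=pcu_df,
    )


def simulate(config: SimConfig | None = None) -> Simulation:
    """Run annotation and junction simulation in one call."""
    config = config or SimConfig()
    return simulate_junctions(config, simulate_annotation(config))


# ---------------------------------------------------------------------------
# file emission


def write_simulation(sim: Simulation, outdir: str | Path) -> dict[str, str]:
    """Write all synthetic inputs as plain-text files; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    write_genepred(sim.annotation.genes, outdir / "genes.genePred")
    paths["genes"] = str(outdir / "genes.genePred")
    write_repeats_bed(sim.annotation.repeats, outdir / "alu.bed")
    paths["repeats"] = str(outdir / "alu.bed")
    jdir = outdir / "junctions"
    jdir.mkdir(exist_ok=True)
    for sid, sub in sim.junctions.groupby("sample_id"):
        p = jdir / f"{sid}.bed"
        with open(p, "w") as fh:
            for r in sub.itertuples(index=False):
                fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.name}\t{r.read_count}\t{r.strand}\n")
        paths[f"junctions/{sid}"] = str(p)
    sim.sample_sheet.to_csv(outdir / "samples.csv")
    paths["sample_sheet"] = str(outdir / "samples.csv")
    truth = {
        "alpha_true": sim.truth.alpha_true,
        "config": asdict(sim.config),
        "circ": sim.truth.circ.reset_index().to_dict(orient="list"),
        "events": sim.truth.events.reset_index().astype(str).to_dict(orient="list"),
        "pcu": sim.truth.pcu.reset_index().to_dict(orient="list"),
    }
    with open(outdir / "truth.json", "w") as fh:
        json.dump(truth, fh)
    paths["truth"] = str(outdir / "truth.json")
    if sim.annotation.sequences is not None:
        with open(outdir / "genome.fa", "w") as fh:
            for chrom, seq in sim.annotation.sequences.items():
                fh.write(f">{chrom}\n")
                for i in range(0, len(seq), 60):
                    fh.write(seq[i : i + 60] + "\n")
        paths["fasta"] = str(outdir / "genome.fa")
    return paths
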