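"""Seeded generator of every synthetic fixture the pipeline needs.

The generator emulates the shape of a multi-environment 16S amplicon study
at desk scale: a rank-structured reference database (default 4 phyla x 2
classes x 2 orders x 2 families x 2 genera = 64 references of ~450 bp, the
V3-V4 amplicon scale), query OTUs evolved into controlled identity bands,
two-parent chimeras, log-normally distributed OTU count tables with planted
abundance summaries, and contigs embedding 16S fragments grouped into bins
that straddle the completeness/contamination quality boundaries.

Identity bands are controlled by post-measurement with the project's own
aligner (rejection sampling), not by mutation count, so band guarantees are
true by construction.  Every generator records machine-readable truth so
downstream tests read truth rather than regenerate it.
"""

from __future__ import annotations

import dataclasses
import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import config
from .classify import NoveltyRank, RankThresholds, best_credible_hit, infer_novelty_rank
from .pairwise import AlignmentParams, ReferenceDB, align
from .placement import ReferenceMSA
from .seqio import (BinMetadata, Lineage, OtuTable, SequenceRecord,
                    write_bin_metadata, write_fasta, write_lineages, write_otu_table)
from .verify import reverse_complement

BASES = np.array(list("ACGT"))


@dataclass
class SynthConfig:
    """Study conditions of the synthetic community."""

    seed: int = 42
    n_phyla: int = 4
    classes_per_phylum: int = 2
    orders_per_class: int = 2
    families_per_order: int = 2
    genera_per_family: int = 2
    species_per_genus: int = 1
    seq_len: int = 450
    # identity of a child to its parent sequence at each hierarchy step;
    # cousins at a rank end up roughly 2x the step divergence apart
    step_identity: dict[str, float] = field(default_factory=lambda: {
        "phylum": 85.0, "class": 91.0, "order": 93.5,
        "family": 95.5, "genus": 97.5, "species": 99.0,
    })
    # best-hit identity targets for planted novelty, mid-band with margin
    band_targets: dict[str, float] = field(default_factory=lambda: {
        "NONE": 97.5, "GENUS": 90.5, "FAMILY": 84.2,
        "ORDER": 80.2, "CLASS": 76.8, "PHYLUM": 71.0,
    })
    indel_rate: float = 0.05       # fraction of query-evolution edits that are indels
    n_samples: int = 8
    lognormal_mu: float = 6.0      # per-cell background count scale (~10k reads/sample)
    lognormal_sigma: float = 1.2
    n_assigned_otus: int = 12
    plants_per_rank: int = 2       # GENUS..PHYLUM novelty plants
    flank_len: int = 300


# --------------------------------------------------------------------------
# Sequence evolution


def random_seq(length: int, rng: np.random.Generator) -> str:
    return "".join(rng.choice(BASES, size=length))


def mutate(seq: str, n_edits: int, rng: np.random.Generator,
           indel_rate: float = 0.0) -> str:
    """Apply point mutations (and indels at ``indel_rate``) to a sequence."""
    s = list(seq)
    for _ in range(n_edits):
        if indel_rate > 0 and rng.random() < indel_rate and len(s) > 2:
            pos = int(rng.integers(0, len(s)))
            if rng.random() < 0.5:
                del s[pos]
            else:
                s.insert(pos, str(rng.choice(BASES)))
        else:
            pos = int(rng.integers(0, len(s)))
            choices = [b for b in "ACGT" if b != s[pos]]
            s[pos] = choices[int(rng.integers(0, 3))]
    return "".join(s)


def evolve(seed_rec: SequenceRecord, target_identity: float,
           rng: np.random.Generator, new_id: str,
           indel_rate: float = 0.0,
           params: AlignmentParams | None = None,
           tolerance: float = 1.0, max_restarts: int = 20) -> SequenceRecord:
    """Evolve a copy of the seed until its realized identity hits the target band.

    The identity is measured with the project's own semiglobal aligner after
    every mutation batch; the realized value is recorded in the description.
    """
    if target_identity >= 100.0:
        return SequenceRecord(id=new_id, seq=seed_rec.seq,
                              desc=f"realized_identity=100.0;target=100.0")
    for _ in range(max_restarts):
        seq = seed_rec.seq
        for _step in range(60):
            cand = SequenceRecord(id=new_id, seq=seq)
            ident = align(cand, seed_rec, params).identity
            if ident <= target_identity + tolerance:
                if ident >= target_identity - tolerance:
                    return SequenceRecord(
                        id=new_id, seq=seq,
                        desc=f"realized_identity={ident:.2f};target={target_identity}")
                break  # overshot: restart with a fresh trajectory
            deficit = len(seq) * (ident - target_identity) / 100.0
            batch = max(1, int(0.6 * deficit))
            seq = mutate(seq, batch, rng, indel_rate)
    raise RuntimeError(f"evolve could not hit identity {target_identity} for {new_id}")


# --------------------------------------------------------------------------
# Reference database


def make_reference_db(cfg: SynthConfig, rng: np.random.Generator
                      ) -> tuple[ReferenceDB, ReferenceMSA]:
    """Rank-structured reference database with an MSA true by construction.

    Evolution along the hierarchy is substitution-only, so ungapped rows line
    up column-for-column; per-phylum deletion windows then create the gapped
    columns that exercise gap-threshold masking (one window shared by half
    the phyla, one private to a single phylum so its columns exceed the 0.70
    gap fraction and get masked).
    """
    root = random_seq(cfg.seq_len, rng)
    records: list[SequenceRecord] = []
    lineages: dict[str, Lineage] = {}
    rows: dict[str, str] = {}

    # two deletion windows: A kept by half the phyla, B kept by one phylum
    win_a = int(rng.integers(40, cfg.seq_len // 2 - 20))
    win_b = int(rng.integers(cfg.seq_len // 2 + 20, cfg.seq_len - 60))
    del_a = (win_a, win_a + 12)
    del_b = (win_b, win_b + 12)

    def _evolve_str(seq: str, ident: float) -> str:
        rec = evolve(SequenceRecord(id="tmp", seq=seq), ident, rng, "tmp")
        return rec.seq

    for p in range(cfg.n_phyla):
        phy_seq = _evolve_str(root, cfg.step_identity["phylum"])
        phy = f"Phy{p + 1:02d}"
        deletions = []
        if p >= cfg.n_phyla // 2:
            deletions.append(del_a)
        if p != 0:
            deletions.append(del_b)
        for c in range(cfg.classes_per_phylum):
            cls_seq = _evolve_str(phy_seq, cfg.step_identity["class"])
            cls = f"{phy}c{c + 1}"
            for o in range(cfg.orders_per_class):
                ord_seq = _evolve_str(cls_seq, cfg.step_identity["order"])
                odr = f"{cls}o{o + 1}"
                for f in range(cfg.families_per_order):
                    fam_seq = _evolve_str(ord_seq, cfg.step_identity["family"])
                    fam = f"{odr}f{f + 1}"
                    for g in range(cfg.genera_per_family):
                        gen_seq = _evolve_str(fam_seq, cfg.step_identity["genus"])
                        gen = f"{fam}g{g + 1}"
                        for s in range(cfg.species_per_genus):
                            sp_seq = _evolve_str(gen_seq, cfg.step_identity["species"])
                            spe = f"{gen}s{s + 1}"
                            rid = f"REF_{spe}"
                            row = list(sp_seq)
                            for start, end in deletions:
                                row[start:end] = ["-"] * (end - start)
                            rows[rid] = "".join(row)
                            records.append(SequenceRecord(
                                id=rid, seq="".join(c for c in row if c != "-")))
                            lineages[rid] = Lineage((
                                "Bacteria", phy, cls, odr, fam, gen, spe))
    db = ReferenceDB(records=records, lineages=lineages)
    return db, ReferenceMSA(rows)


def plant_novel(db: ReferenceDB, rank: NoveltyRank, rng: np.random.Generator,
                new_id: str, cfg: SynthConfig,
                thresholds: RankThresholds | None = None,
                margin: float = 1.0, max_tries: int = 60
                ) -> tuple[SequenceRecord, str, float]:
    """Rejection-sample a query whose best db identity sits inside the rank band.

    Returns (record, parent_ref_id, realized_best_identity); the realized
    identity is guaranteed >= ``margin`` points inside the band on both sides.
    """
    t = thresholds or RankThresholds()
    target = cfg.band_targets[rank.name]
    edges = {
        NoveltyRank.NONE: (t.genus, 100.0),
        NoveltyRank.GENUS: (t.family, t.genus),
        NoveltyRank.FAMILY: (t.order, t.family),
        NoveltyRank.ORDER: (t.class_, t.order),
        NoveltyRank.CLASS: (t.phylum, t.class_),
        NoveltyRank.PHYLUM: (t.artifact_floor, t.phylum),
    }[rank]
    for _ in range(max_tries):
        parent = db.records[int(rng.integers(0, len(db.records)))]
        rec = evolve(parent, target, rng, new_id, indel_rate=cfg.indel_rate)
        hit = best_credible_hit(rec, db)
        best = hit.identity if hit is not None else 0.0
        lo_ok = best > edges[0] + margin
        hi_ok = best <= edges[1] - margin if rank != NoveltyRank.NONE else best <= edges[1]
        if lo_ok and hi_ok and infer_novelty_rank(best, t) == rank:
            return rec, parent.id, best
    raise RuntimeError(f"could not plant a {rank.name}-band query")


def make_chimera(parent_a: SequenceRecord, parent_b: SequenceRecord,
                 breakpoint_fraction: float, rng: np.random.Generator,
                 new_id: str) -> tuple[SequenceRecord, int]:
    """Prefix of parent_a + suffix of parent_b at the given fractional breakpoint."""
    c = int(round(breakpoint_fraction * len(parent_a.seq)))
    c = max(1, min(len(parent_a.seq) - 1, c))
    suffix_start = min(c, len(parent_b.seq) - 1)
    seq = parent_a.seq[:c] + parent_b.seq[suffix_start:]
    return SequenceRecord(id=new_id, seq=seq), c


def make_otu_table(otu_ids: list[str], n_samples: int, rng: np.random.Generator,
                   planted_abundances: dict[str, float] | None = None,
                   planted_totals: dict[str, int] | None = None,
                   lognormal_mu: float = 6.0, lognormal_sigma: float = 1.2
                   ) -> OtuTable:
    """Log-normal background counts with planted abundance summaries.

    ``planted_abundances`` maps OTU ids to a target abundance summary in
    percent (sum over samples of per-sample relative abundance x 100); the
    planted rows are solved against the background column sums so the
    realized summary lands at the target.  ``planted_totals`` instead pins a
    row's total read count (for min-read boundary cases).
    """
    planted_abundances = planted_abundances or {}
    planted_totals = planted_totals or {}
    sample_ids = [f"S{j + 1:02d}" for j in range(n_samples)]
    counts = np.zeros((len(otu_ids), n_samples), dtype=np.int64)
    background = [
        i for i, o in enumerate(otu_ids)
        if o not in planted_abundances and o not in planted_totals
    ]
    for i in background:
        counts[i] = np.floor(rng.lognormal(lognormal_mu, lognormal_sigma, n_samples)).astype(np.int64)
    for otu, total in planted_totals.items():
        i = otu_ids.index(otu)
        base = total // n_samples
        counts[i] = base
        counts[i, : total - base * n_samples] += 1
    col_sums = counts.sum(axis=0)
    for otu, summary in planted_abundances.items():
        i = otu_ids.index(otu)
        r = summary / 100.0 / n_samples  # per-sample relative abundance
        if not (0 <= r < 1):
            raise ValueError(f"unachievable abundance summary {summary} for {otu}")
        counts[i] = np.round(r * col_sums / (1.0 - r)).astype(np.int64)
    return OtuTable(otu_ids=list(otu_ids), sample_ids=sample_ids, counts=counts)


def embed_in_contig(seq: SequenceRecord, flank_len: int, mutation_rate: float,
                    rng: np.random.Generator, contig_id: str
                    ) -> tuple[SequenceRecord, dict]:
    """A contig with a (mutated) copy of the sequence between random flanks."""
    n_mut = int(round(mutation_rate * len(seq.seq)))
    core = mutate(seq.seq, n_mut, rng) if n_mut else seq.seq
    left = random_seq(flank_len, rng)
    right = random_seq(flank_len, rng)
    contig = SequenceRecord(id=contig_id, seq=left + core + right)
    truth = {
        "contig_id": contig_id,
        "embedded_mdms": seq.id,
        "start": flank_len,
        "end": flank_len + len(core),
        "mutation_rate": mutation_rate,
    }
    return contig, truth


#: Bin quality spectrum straddling the completeness>=50 / contamination<=10
#: boundaries; the first two mirror observed draft-genome quality values.
BIN_QUALITY_SPECTRUM = [
    ("bin.1", 83.51, 0.959, 1_528_181),   # comfortably passing
    ("bin.2", 54.38, 0.0, 529_863),       # low but passing completeness
    ("bin.3", 49.9, 0.0, 800_000),        # just under the completeness floor
    ("bin.4", 60.0, 10.1, 1_200_000),     # just over the contamination ceiling
    ("bin.5", 96.47, 0.352, 2_729_365),   # near-complete
]


def assign_bins(contigs: list[SequenceRecord], rng: np.random.Generator,
                leave_unbinned: int = 1) -> dict[str, BinMetadata]:
    """Distribute contigs into the quality-spectrum bins; some stay unbinned."""
    bins = {
        bid: BinMetadata(bin_id=bid, completeness=comp, contamination=cont, size_bp=size)
        for bid, comp, cont, size in BIN_QUALITY_SPECTRUM
    }
    bin_ids = list(bins)
    assignable = contigs[: len(contigs) - leave_unbinned] if leave_unbinned else contigs
    for i, contig in enumerate(assignable):
        bins[bin_ids[i % len(bin_ids)]].contig_ids.add(contig.id)
    return bins


# --------------------------------------------------------------------------
# Full dataset


def generate_dataset(cfg: SynthConfig, outdir: str | os.PathLike) -> Path:
    """Write the complete synthetic input directory plus truth tables.

    Contents: refs.fasta + refs_lineage.tsv + refs_aln.fasta (reference DB),
    otus.fasta + otu_table.tsv (+ .biom.json twin), contigs.fasta + bins.tsv,
    primers.tsv, and truth/*.tsv recording what was planted where.
    """
    out = Path(outdir)
    (out / "truth").mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)

    db, msa = make_reference_db(cfg, rng)
    write_fasta(db.records, out / "refs.fasta")
    write_lineages(db.lineages, out / "refs_lineage.tsv")
    msa.to_fasta(out / "refs_aln.fasta")

    otus: list[SequenceRecord] = []
    truth_rows: list[dict] = []
    chimera_rows: list[dict] = []
    counter = 0

    def _next_id() -> str:
        nonlocal counter
        counter += 1
        return f"OTU_{counter:04d}"

    # ordinary, assignable community members (best identity ~97.5%)
    for _ in range(cfg.n_assigned_otus):
        parent = db.records[int(rng.integers(0, len(db.records)))]
        rec = evolve(parent, cfg.band_targets["NONE"], rng, _next_id(),
                     indel_rate=cfg.indel_rate)
        otus.append(rec)
        truth_rows.append({"otu_id": rec.id, "kind": "assigned", "planted_rank": "NONE",
                           "parent": parent.id, "is_planted_mdms": False})

    # novelty plants, one band per rank; abundance pinned under the cutoff so
    # only the designated MDMS set below is selected
    background_abund: dict[str, float] = {}
    for rank in (NoveltyRank.GENUS, NoveltyRank.FAMILY, NoveltyRank.ORDER,
                 NoveltyRank.CLASS, NoveltyRank.PHYLUM):
        for _ in range(cfg.plants_per_rank):
            rec, parent_id, realized = plant_novel(db, rank, rng, _next_id(), cfg)
            otus.append(rec)
            background_abund[rec.id] = float(rng.uniform(0.1, 0.35))
            truth_rows.append({"otu_id": rec.id, "kind": "novel",
                               "planted_rank": rank.name, "parent": parent_id,
                               "realized_best_identity": round(realized, 2),
                               "is_planted_mdms": False})

    # abundant clean MDMS: deep-novelty plants promoted by abundance below
    mdms_clean: list[SequenceRecord] = []
    for rank in (NoveltyRank.FAMILY, NoveltyRank.ORDER, NoveltyRank.CLASS,
                 NoveltyRank.PHYLUM):
        rec, parent_id, realized = plant_novel(db, rank, rng, _next_id(), cfg)
        otus.append(rec)
        mdms_clean.append(rec)
        truth_rows.append({"otu_id": rec.id, "kind": "novel",
                           "planted_rank": rank.name, "parent": parent_id,
                           "realized_best_identity": round(realized, 2),
                           "is_planted_mdms": True})

    # chimeric MDMS: bimeras of two genus-band plants rooted in different
    # phyla — each half echoes a different reference at ~90%, the whole
    # matches nothing above the unassigned line
    mdms_chimeric: list[SequenceRecord] = []
    for _ in range(2):
        while True:
            pa, pa_parent, _ = plant_novel(db, NoveltyRank.GENUS, rng,
                                           f"parentA_{counter}", cfg)
            pb, pb_parent, _ = plant_novel(db, NoveltyRank.GENUS, rng,
                                           f"parentB_{counter}", cfg)
            if db.lineages[pa_parent].ranks[1] != db.lineages[pb_parent].ranks[1]:
                break
        frac = float(rng.uniform(0.4, 0.6))
        rec, bp = make_chimera(pa, pb, frac, rng, _next_id())
        otus.append(rec)
        mdms_chimeric.append(rec)
        truth_rows.append({"otu_id": rec.id, "kind": "chimera", "planted_rank": "",
                           "parent": f"{pa.id}|{pb.id}", "is_planted_mdms": True})
        chimera_rows.append({"otu_id": rec.id, "parent_a": pa.id,
                             "parent_b": pb.id, "breakpoint": bp})

    # negative controls for the selection gates
    low_reads = evolve(db.records[0], cfg.band_targets["ORDER"], rng, _next_id(),
                       indel_rate=cfg.indel_rate)
    otus.append(low_reads)
    truth_rows.append({"otu_id": low_reads.id, "kind": "novel_low_reads",
                       "planted_rank": "ORDER", "parent": db.records[0].id,
                       "is_planted_mdms": False})
    low_abund, la_parent, _ = plant_novel(db, NoveltyRank.CLASS, rng, _next_id(), cfg)
    otus.append(low_abund)
    truth_rows.append({"otu_id": low_abund.id, "kind": "novel_low_abundance",
                       "planted_rank": "CLASS", "parent": la_parent,
                       "is_planted_mdms": False})

    write_fasta(otus, out / "otus.fasta")

    planted_abund = {rec.id: s for rec, s in
                     zip(mdms_clean + mdms_chimeric, (5.0, 3.0, 2.0, 1.2, 2.5, 1.6))}
    planted_abund.update(background_abund)
    planted_abund[low_abund.id] = 0.1   # unassigned but below the 0.5% cutoff
    table = make_otu_table(
        [r.id for r in otus], cfg.n_samples, rng,
        planted_abundances=planted_abund,
        planted_totals={low_reads.id: 30},  # below the 50-read floor
        lognormal_mu=cfg.lognormal_mu, lognormal_sigma=cfg.lognormal_sigma,
    )
    write_otu_table(table, out / "otu_table.tsv")

    # contigs: clean MDMS embedded at varying divergence + background contigs
    contigs: list[SequenceRecord] = []
    contig_truth: list[dict] = []
    embed_specs = [
        (mdms_clean[0], 0.005), (mdms_clean[1], 0.01),   # should pass >96%
        (mdms_clean[2], 0.05),                            # ~95%: below the line
        (mdms_clean[3], 0.01),
    ]
    for i, (rec, rate) in enumerate(embed_specs):
        contig, tr = embed_in_contig(rec, cfg.flank_len, rate, rng, f"NODE_{i + 1}")
        contigs.append(contig)
        contig_truth.append(tr)
    for i in range(2):  # background contigs without any MDMS
        contigs.append(SequenceRecord(id=f"NODE_BG{i + 1}",
                                      seq=random_seq(2000, rng)))
        contig_truth.append({"contig_id": f"NODE_BG{i + 1}", "embedded_mdms": "",
                             "start": -1, "end": -1, "mutation_rate": 0.0})
    write_fasta(contigs, out / "contigs.fasta")
    bins = assign_bins(contigs, rng, leave_unbinned=1)
    write_bin_metadata(bins, out / "bins.tsv")
    contig_to_bin = {c: b.bin_id for b in bins.values() for c in b.contig_ids}
    for tr in contig_truth:
        tr["bin_id"] = contig_to_bin.get(tr["contig_id"], "")

    # perfect-match primer pairs off the ends of each clean MDMS
    primer_rows = []
    for rec in mdms_clean:
        fwd = rec.seq[5:25]
        rev = reverse_complement(rec.seq[-25:-5])
        primer_rows.append({"name": rec.id, "fwd": fwd, "rev": rev})
    pd.DataFrame(primer_rows).to_csv(out / "primers.tsv", sep="\t", index=False)

    pd.DataFrame(truth_rows).to_csv(out / "truth" / "otus.tsv", sep="\t", index=False)
    pd.DataFrame(chimera_rows).to_csv(out / "truth" / "chimeras.tsv", sep="\t", index=False)
    pd.DataFrame(contig_truth).to_csv(out / "truth" / "contigs.tsv", sep="\t", index=False)
    with open(out / "truth" / "synth_config.txt", "w") as fh:
        for f_ in dataclasses.fields(cfg):
            fh.write(f"{f_.name}\t{getattr(cfg, f_.name)}\n")
    return out
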