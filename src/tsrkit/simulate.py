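"""Synthetic data generator for the full TSR analysis pipeline.

Emits a random genome with planted transcription start regions of known
class, plus every signal the pipeline consumes: csRNA 5'-end profiles,
short-RNA input contamination at non-initiating loci, strand-specific
RNA-seq read starts downstream of stable TSSs only, GRO-seq gene-body
signal, and STARR-seq activities with class-dependent means.  The planted
truth table makes every stage's output checkable without any external
download.

Planted element anatomy (strand-relative):

- a TATAAA box at -31..-26 and a C/A initiator at -1/+1, so sequence
  metaplots show the canonical core-promoter signature;
- csRNA 5' ends multinomial around the TSS (sharp: 85% at the mode;
  dispersed: discretized Laplace over +/-50 bp);
- stable elements get >= 5 normalized RNA-seq read starts in the
  -100..+500 stability window and further gene-body reads to +2,000;
  unstable elements get uniform [0, 1) leakage, safely below the
  threshold of 2;
- GRO-seq covers -100..+3,000 at a class-dependent level.

All randomness derives from ``config.seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import (
    CoverageTrack,
    EndProfile,
    GeneAnnotation,
    GenomeSequence,
    NORM_FACTOR,
    Transcript,
)


class ConfigError(ValueError):
    pass


@dataclass
class SimulationConfig:
    genome_length: int = 2_000_000
    n_genes: int = 100
    n_distal: int | None = None          # derived from fraction_distal unless set
    fraction_unstable: float = 0.3
    fraction_bidirectional: float = 0.1
    fraction_distal: float = 0.2
    fraction_antisense: float = 0.05
    csrna_depth: float = 1e7             # total aligned reads (library metadata)
    rna_depth: float = 1e7
    input_contaminant_rate: float = 0.1  # contaminant loci per planted element
    tss_shape: str = "sharp"             # "sharp" | "dispersed"
    dispersion_width: int = 20
    noise_rate: float = 1e-5             # background 5' ends per bp per strand
    starr_effects: dict = field(
        default_factory=lambda: {
            "no_transcription": 2.0,
            "UU": 5.0,
            "U": 6.5,
            "US": 8.0,
            "stable": 11.0,
        }
    )
    starr_sd: float = 1.0
    starr_txn_coupling: float = 1.5  # activity units per log10 of csRNA signal
    starr_region_length: int = 200
    starr_short_fragment_rate: float = 0.1
    n_no_transcription: int = 60
    seed: int = 0

    # layout constants: each planted locus owns a slot wide enough for the
    # +/-3 kb analysis windows around it
    slot: int = 7000
    margin: int = 5000

    def __post_init__(self) -> None:
        for name in ("fraction_unstable", "fraction_bidirectional", "fraction_distal", "fraction_antisense"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        if self.csrna_depth <= 0 or self.rna_depth <= 0:
            raise ConfigError("sequencing depths must be positive")
        if self.tss_shape not in ("sharp", "dispersed"):
            raise ConfigError(f"unknown tss_shape {self.tss_shape!r}")


@dataclass
class TruthTable:
    """Planted-element catalogue: the ground truth for recovery tests."""

    elements: pd.DataFrame      # element_id chrom strand tss stability context partner_id style cs_signal rna_score
    contaminants: pd.DataFrame  # locus_id chrom strand pos cs_reads input_reads
    open_regions: pd.DataFrame  # chrom start end name  (untranscribed open chromatin)
    genome_length: int

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        self.elements.to_csv(outdir / "truth_elements.tsv", sep="\t", index=False)
        self.contaminants.to_csv(outdir / "truth_contaminants.tsv", sep="\t", index=False)
        self.open_regions.to_csv(outdir / "truth_open_regions.tsv", sep="\t", index=False)

    @classmethod
    def read(cls, outdir, genome_length: int) -> "TruthTable":
        outdir = Path(outdir)
        return cls(
            elements=pd.read_csv(outdir / "truth_elements.tsv", sep="\t", keep_default_na=False),
            contaminants=pd.read_csv(outdir / "truth_contaminants.tsv", sep="\t", keep_default_na=False),
            open_regions=pd.read_csv(outdir / "truth_open_regions.tsv", sep="\t", keep_default_na=False),
            genome_length=genome_length,
        )


CHROM = "chr1"


def _plant(seq: list[str], pos: int, strand: str, offset_motif: int, motif: str) -> None:
    """Write a motif at a strand-relative offset; '-' strand writes the
    reverse complement so the sense sequence reads the motif."""
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    if strand == "+":
        start = pos + offset_motif
        for i, b in enumerate(motif):
            if 0 <= start + i < len(seq):
                seq[start + i] = b
    else:
        start = pos - offset_motif
        for i, b in enumerate(motif):
            p = start - i
            if 0 <= p < len(seq):
                seq[p] = comp[b]


def simulate_genome(config: SimulationConfig) -> tuple[GenomeSequence, GeneAnnotation, TruthTable]:
    """Random genome + annotation + planted-element truth table.

    Gene 5' ends are placed on a jittered grid that guarantees >= 4 kb
    between locus anchors.  Each promoter element sits exactly at its
    gene's annotated 5' end; distal elements, input-contaminant loci and
    untranscribed open-chromatin regions get their own slots.
    """
    rng = np.random.default_rng(config.seed)
    fd = config.fraction_distal
    if config.n_distal is not None:
        n_distal = config.n_distal
    elif config.n_genes > 0:
        n_distal = int(round(config.n_genes * fd / (1.0 - fd))) if fd < 1.0 else 0
    else:
        n_distal = 10 if fd > 0 else 0
    n_primary = config.n_genes + n_distal
    n_cont = int(round(config.input_contaminant_rate * n_primary))
    n_slots = n_primary + n_cont + config.n_no_transcription
    needed = 2 * config.margin + n_slots * config.slot
    if config.genome_length < needed:
        raise ConfigError(
            f"genome_length {config.genome_length} too short for {n_slots} loci "
            f"(need >= {needed} bp at 4 kb spacing)"
        )

    seq = rng.choice(list("ACGT"), size=config.genome_length).tolist()

    jitter_span = config.slot - 4000
    anchors = [
        config.margin + i * config.slot + int(rng.integers(0, jitter_span))
        for i in range(n_slots)
    ]
    anchors = [int(a) for a in rng.permutation(anchors)]
    elem_anchors = anchors[:n_primary]
    cont_anchors = anchors[n_primary : n_primary + n_cont]
    open_anchors = anchors[n_primary + n_cont :]

    distal_idx = set(rng.choice(n_primary, size=n_distal, replace=False).tolist()) if n_distal else set()

    transcripts: list[Transcript] = []
    rows: list[dict] = []
    counter = 0

    def _new_id() -> str:
        nonlocal counter
        counter += 1
        return f"E{counter:05d}"

    for i, anchor in enumerate(elem_anchors):
        strand = "+" if rng.random() < 0.5 else "-"
        is_distal = i in distal_idx
        unstable = rng.random() < config.fraction_unstable
        cs_signal = float(np.round(10 ** rng.uniform(2.0, 3.0)))
        rna_score = float(rng.uniform(5.0, 40.0)) if not unstable else float(rng.uniform(0.0, 1.0))
        eid = _new_id()
        row = {
            "element_id": eid,
            "chrom": CHROM,
            "strand": strand,
            "tss": anchor,
            "stability": "unstable" if unstable else "stable",
            "context": "distal" if is_distal else "promoter_sense",
            "partner_id": "",
            "style": "",
            "cs_signal": cs_signal,
            "rna_score": rna_score,
        }
        rows.append(row)
        _plant(seq, anchor, strand, -31, "TATAAA")
        _plant(seq, anchor, strand, -1, "CA")

        if not is_distal:
            glen = int(rng.integers(1000, 3001))
            if strand == "+":
                g_start, g_end = anchor, min(anchor + glen, config.genome_length)
            else:
                g_start, g_end = max(0, anchor - glen + 1), anchor + 1
            gid = f"g{i + 1:05d}"
            transcripts.append(
                Transcript(
                    transcript_id=f"t{i + 1:05d}",
                    gene_id=gid,
                    chrom=CHROM,
                    strand=strand,
                    start=g_start,
                    end=g_end,
                    n_exons=2,
                )
            )

        # divergent partner (bidirectional unit)
        if rng.random() < config.fraction_bidirectional:
            u = int(rng.integers(60, 221))
            p_strand = "-" if strand == "+" else "+"
            p_pos = anchor - u if strand == "+" else anchor + u
            p_unstable = rng.random() < config.fraction_unstable
            # partner kept weaker than the primary so the primary stays the
            # strongest TSR of the unit
            p_signal = float(np.round(cs_signal * rng.uniform(0.3, 0.8)))
            pid = _new_id()
            rows.append(
                {
                    "element_id": pid,
                    "chrom": CHROM,
                    "strand": p_strand,
                    "tss": p_pos,
                    "stability": "unstable" if p_unstable else "stable",
                    "context": "divergent" if not is_distal else "distal",
                    "partner_id": eid,
                    "style": "",
                    "cs_signal": p_signal,
                    "rna_score": float(rng.uniform(5.0, 40.0)) if not p_unstable else float(rng.uniform(0.0, 1.0)),
                }
            )
            row["partner_id"] = pid
            _plant(seq, p_pos, p_strand, -31, "TATAAA")
            _plant(seq, p_pos, p_strand, -1, "CA")
        # convergent antisense element inside the gene's TSS region
        elif not is_distal and rng.random() < config.fraction_antisense:
            u = int(rng.integers(50, 251))
            a_strand = "-" if strand == "+" else "+"
            a_pos = anchor + u if strand == "+" else anchor - u
            a_unstable = rng.random() < max(config.fraction_unstable, 0.5)
            aid = _new_id()
            rows.append(
                {
                    "element_id": aid,
                    "chrom": CHROM,
                    "strand": a_strand,
                    "tss": a_pos,
                    "stability": "unstable" if a_unstable else "stable",
                    "context": "antisense",
                    "partner_id": "",
                    "style": "",
                    "cs_signal": float(np.round(10 ** rng.uniform(2.0, 2.5))),
                    "rna_score": float(rng.uniform(5.0, 40.0)) if not a_unstable else float(rng.uniform(0.0, 1.0)),
                }
            )
            _plant(seq, a_pos, a_strand, -1, "CA")

    elements = pd.DataFrame(
        rows,
        columns=[
            "element_id", "chrom", "strand", "tss", "stability", "context",
            "partner_id", "style", "cs_signal", "rna_score",
        ],
    )
    elements["style"] = derive_styles(elements)

    cont_rows = []
    for k, anchor in enumerate(cont_anchors):
        strand = "+" if rng.random() < 0.5 else "-"
        cs_reads = int(rng.integers(30, 81))
        cont_rows.append(
            {
                "locus_id": f"C{k + 1:04d}",
                "chrom": CHROM,
                "strand": strand,
                "pos": anchor,
                "cs_reads": cs_reads,
                "input_reads": int(cs_reads * rng.uniform(3.0, 5.0)),
            }
        )
    contaminants = pd.DataFrame(
        cont_rows, columns=["locus_id", "chrom", "strand", "pos", "cs_reads", "input_reads"]
    )

    half = config.starr_region_length // 2
    open_regions = pd.DataFrame(
        {
            "chrom": CHROM,
            "start": [a - half for a in open_anchors],
            "end": [a + half for a in open_anchors],
            "name": [f"OCR{k + 1:04d}" for k in range(len(open_anchors))],
        }
    )

    genome = GenomeSequence({CHROM: "".join(seq)})
    annotation = GeneAnnotation(sorted(transcripts, key=lambda t: (t.chrom, t.start, t.transcript_id)))
    truth = TruthTable(
        elements=elements,
        contaminants=contaminants,
        open_regions=open_regions,
        genome_length=config.genome_length,
    )
    return genome, annotation, truth


def derive_styles(elements: pd.DataFrame) -> pd.Series:
    """S/U/US/UU from planted stability and partner links."""
    stab = dict(zip(elements["element_id"], elements["stability"]))
    partner_of = {}
    for r in elements.itertuples(index=False):
        if r.partner_id:
            partner_of[r.element_id] = r.partner_id
            partner_of.setdefault(r.partner_id, r.element_id)
    styles = []
    for r in elements.itertuples(index=False):
        p = partner_of.get(r.element_id, "")
        if stab[r.element_id] == "stable":
            styles.append("S")
        elif not p:
            styles.append("U")
        else:
            styles.append("US" if stab[p] == "stable" else "UU")
    return pd.Series(styles, index=elements.index)


# ---------------------------------------------------------------------------
# signal simulation
# ---------------------------------------------------------------------------


def _tss_offsets(rng, n: int, shape: str, width: int) -> np.ndarray:
    """Strand-relative 5'-end offsets around a planted mode."""
    if shape == "sharp":
        at_mode = rng.random(n) < 0.85
        spread = np.round(rng.laplace(0.0, 3.0, size=n)).astype(int)
        spread = np.clip(spread, -15, 15)
        offs = np.where(at_mode, 0, spread)
    else:
        offs = np.round(rng.laplace(0.0, max(1.0, width / 2.0), size=n)).astype(int)
        offs = np.clip(offs, -50, 50)
    return offs


def simulate_signals(
    truth: TruthTable, config: SimulationConfig
) -> tuple[EndProfile, EndProfile, CoverageTrack, CoverageTrack]:
    """csRNA + input 5'-end profiles and RNA-seq + GRO-seq tracks."""
    rng = np.random.default_rng([config.seed, 1])
    L = truth.genome_length
    cs = EndProfile(total_aligned_reads=config.csrna_depth)
    inp = EndProfile(total_aligned_reads=config.csrna_depth)
    rna = CoverageTrack(total_aligned_reads=config.rna_depth)
    gro = CoverageTrack(total_aligned_reads=config.rna_depth)
    cs_scale = config.csrna_depth / NORM_FACTOR
    rna_scale = config.rna_depth / NORM_FACTOR

    def _oriented(pos: int, strand: str, offsets: np.ndarray) -> np.ndarray:
        gpos = pos + offsets if strand == "+" else pos - offsets
        return np.clip(gpos, 0, L - 1)

    for e in truth.elements.itertuples(index=False):
        n_reads = int(round(e.cs_signal * cs_scale))
        offs = _tss_offsets(rng, n_reads, config.tss_shape, config.dispersion_width)
        cs.add_positions(e.chrom, e.strand, _oriented(e.tss, e.strand, offs).tolist())

        n_win = int(round(e.rna_score * rna_scale))
        if n_win:
            offs = rng.integers(1, 501, size=n_win)
            rna.add_positions(e.chrom, e.strand, _oriented(e.tss, e.strand, offs).tolist())
        if e.stability == "stable":
            n_body = int(round(3 * e.rna_score * rna_scale))
            offs = rng.integers(501, 2001, size=n_body)
            rna.add_positions(e.chrom, e.strand, _oriented(e.tss, e.strand, offs).tolist())

        stable = e.stability == "stable"
        n_prox = rng.poisson(120 if stable else 60)
        n_body = rng.poisson(240 if stable else 120)
        offs = np.concatenate(
            [rng.integers(-100, 301, size=n_prox), rng.integers(301, 3001, size=n_body)]
        )
        gro.add_positions(e.chrom, e.strand, _oriented(e.tss, e.strand, offs).tolist())

    for c in truth.contaminants.itertuples(index=False):
        cs_offs = rng.integers(-2, 3, size=int(round(c.cs_reads * cs_scale)))
        in_offs = rng.integers(-2, 3, size=int(round(c.input_reads * cs_scale)))
        cs.add_positions(c.chrom, c.strand, _oriented(c.pos, c.strand, cs_offs).tolist())
        inp.add_positions(c.chrom, c.strand, _oriented(c.pos, c.strand, in_offs).tolist())

    # uniform background 5' ends (below the TSS threshold at default depth)
    for track in (cs, inp):
        for strand in ("+", "-"):
            n_bg = rng.poisson(config.noise_rate * L)
            pos = rng.integers(0, L, size=n_bg)
            track.add_positions(CHROM, strand, pos.tolist())
    return cs, inp, rna, gro


def simulate_starr(truth: TruthTable, config: SimulationConfig) -> pd.DataFrame:
    """STARR fragment/peak activities around planted units.

    One peak per transcription unit (a bidirectional pair is one unit,
    centred between its two TSSs) plus one per untranscribed open region,
    with activity = class mean + Gaussian noise (clipped at 0), and a
    configurable admixture of short (20-50 bp) fragments that exercise
    the length filter.  Transcribed units additionally receive
    ``starr_txn_coupling`` activity units per log10 of their planted csRNA
    signal (centred at 10^2.5), emulating the positive coupling between
    initiation strength and enhancer activity seen in reporter assays.
    """
    rng = np.random.default_rng([config.seed, 2])
    effects = config.starr_effects
    for key in ("no_transcription", "stable", "U", "UU", "US"):
        if key not in effects:
            raise ConfigError(f"starr_effects missing class {key!r}")
    half = config.starr_region_length // 2

    elems = truth.elements
    partner = dict(zip(elems["element_id"], elems["partner_id"]))
    seen = set()
    units = []  # (center, style_key, unit_name)
    by_id = {r.element_id: r for r in elems.itertuples(index=False)}
    for r in elems.itertuples(index=False):
        if r.element_id in seen:
            continue
        p = partner.get(r.element_id, "")
        if p:
            seen.add(p)
            other = by_id[p]
            center = (r.tss + other.tss) // 2
            if r.stability == "unstable" or other.stability == "unstable":
                key = "UU" if r.stability == other.stability == "unstable" else "US"
            else:
                key = "stable"
        else:
            center = r.tss
            key = "stable" if r.stability == "stable" else "U"
        seen.add(r.element_id)
        units.append((center, key, r.element_id, float(r.cs_signal)))

    rows = []
    for center, key, name, signal in units:
        mean = effects[key] + config.starr_txn_coupling * (np.log10(max(signal, 1.0)) - 2.5)
        act = max(0.0, float(rng.normal(mean, config.starr_sd)))
        rows.append(
            {"chrom": CHROM, "start": center - half, "end": center + half,
             "name": f"SP_{name}", "activity": act, "planted_class": key}
        )
    for r in truth.open_regions.itertuples(index=False):
        act = max(0.0, float(rng.normal(effects["no_transcription"], config.starr_sd)))
        rows.append(
            {"chrom": r.chrom, "start": int(r.start), "end": int(r.end),
             "name": f"SP_{r.name}", "activity": act, "planted_class": "no_transcription"}
        )

    n_short = int(round(config.starr_short_fragment_rate * len(units)))
    if n_short and units:
        pick = rng.choice(len(units), size=n_short, replace=True)
        for j, k in enumerate(pick):
            center = units[int(k)][0]
            flen = int(rng.integers(20, 51))
            start = center + int(rng.integers(-half, half - flen + 1))
            act = max(0.0, float(rng.normal(effects["no_transcription"], config.starr_sd)))
            rows.append(
                {"chrom": CHROM, "start": start, "end": start + flen,
                 "name": f"SF{j + 1:04d}", "activity": act, "planted_class": "short_fragment"}
            )
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "activity", "planted_class"])
    return df.sort_values(["chrom", "start", "name"], kind="mergesort").reset_index(drop=True)


def simulate_all(config: SimulationConfig):
    """Convenience wrapper: genome, annotation, truth, all signal tracks
    and the STARR table in one call."""
    genome, annotation, truth = simulate_genome(config)
    cs, inp, rna, gro = simulate_signals(truth, config)
    starr = simulate_starr(truth, config)
    return genome, annotation, truth, cs, inp, rna, gro, starr
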