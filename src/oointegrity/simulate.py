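"""Synthetic single-oocyte dataset generator with a planted-truth ledger.

The generator emulates the study design every downstream stage consumes:
two groups of single cells (control vs mutant oocytes, one alignment
library per cell), negative-binomially expressed genes on a synthetic
chromosome, planted junction-usage shifts (cassette-exon skipping with a
configured delta-PSI), three SINE-like repeat families whose element copies
derive from a family consensus by i.i.d. point mutations, one family
planted as upregulated in the mutant group with exon-biased genomic
placement, crosslink tags enriched inside enhanced exons, and FRET trace
archetypes (control: a single pre-GVBD activation peak; mutant: a bounded
mean-reverting walk with no peak).

Reads are generated directly as aligned SAM records -- read mapping is out
of scope, and the pipeline consumes alignments. Every planted quantity is
recorded in a truth ledger sufficient to recompute the expected summaries
exactly. The same seed yields byte-identical output files.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

BASES = np.array(list("ACGT"))
CHROM = "chrT"
CONTROL, MUTANT = "control", "mutant"

__all__ = [
    "RepeatFamilyConfig",
    "SimulationConfig",
    "FretConfig",
    "SyntheticDataset",
    "generate_dataset",
    "generate_fret_traces",
    "null_config",
]


@dataclass
class RepeatFamilyConfig:
    name: str
    class_: str = "SINE"
    family: str = "B2like"
    consensus_len: int = 180
    n_elements: int = 300
    mutation_rate: float = 0.05
    log2fc: float = 0.0            # planted mutant/control fold change
    exon_frac: float = 0.1         # genomic placement mixture
    intron_frac: float = 0.4
    strand_concordance: float = 0.5


def _default_families() -> list[RepeatFamilyConfig]:
    return [
        RepeatFamilyConfig("B2like_1", log2fc=3.0, exon_frac=0.5,
                           intron_frac=0.3, strand_concordance=0.8),
        RepeatFamilyConfig("B2like_2"),
        RepeatFamilyConfig("B2like_3"),
    ]


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic dataset.

    Defaults are the standard conditions the pipeline is validated under:
    10 + 10 cells, 200 five-exon genes, 20 up-skip events with
    delta-PSI = 0.5 (plus 10 down and 30 unregulated cassette events so the
    splicing map has silenced and control sets), 3 repeat families x 300
    elements with one family at log2FC = 3 and exon-biased placement, and
    5x crosslink enrichment inside enhanced exons.
    """

    seed: int = 0
    n_control: int = 10
    n_mutant: int = 10
    # gene model geometry
    n_genes: int = 200
    exons_per_gene: int = 5
    exon_len: int = 250
    intron_len: int = 400
    intergenic_gap: int = 1200
    # expression
    gene_read_mean: float = 60.0
    gene_dispersion: float = 0.2        # NB: var = m + disp * m^2
    splice_read_fraction: float = 0.6
    read_len: int = 60
    junction_anchor: int = 30
    # planted differential expression
    n_de_genes: int = 20
    de_fold: float = 4.0
    # planted splicing events
    n_skip_up: int = 20
    n_skip_down: int = 10
    n_skip_null: int = 30
    delta_psi: float = 0.5
    base_skip_usage: float = 0.15
    null_skip_usage: float = 0.30
    # repeats
    families: list[RepeatFamilyConfig] = field(default_factory=_default_families)
    repeat_read_mean: float = 3.0       # per-element per-cell expected reads
    # crosslinks
    xlink_base_rate: float = 0.02       # tags per nt around events
    xlink_enrichment: float = 5.0       # multiplier inside enhanced exons
    xlink_flank: int = 400

    def validate(self) -> None:
        for name, p in [("splice_read_fraction", self.splice_read_fraction),
                        ("base_skip_usage", self.base_skip_usage),
                        ("null_skip_usage", self.null_skip_usage),
                        ("delta_psi", self.delta_psi)]:
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.base_skip_usage + self.delta_psi > 1.0:
            raise ValueError("base_skip_usage + delta_psi exceeds 1")
        for n in (self.n_control, self.n_mutant, self.n_genes,
                  self.n_skip_up, self.n_skip_down, self.n_skip_null,
                  self.n_de_genes):
            if n < 0:
                raise ValueError("counts must be >= 0")
        planted = (self.n_skip_up + self.n_skip_down + self.n_skip_null
                   + self.n_de_genes)
        if planted > self.n_genes:
            raise ValueError("more planted genes than genes")
        if self.exons_per_gene < 3 and (self.n_skip_up or self.n_skip_down
                                        or self.n_skip_null):
            raise ValueError("skipping events need >= 3 exons per gene")
        n_junctions = self.exons_per_gene - 1
        if self.gene_read_mean * self.splice_read_fraction < n_junctions:
            raise ValueError("expected junction reads per gene fall below the "
                             "number of junction events (infeasible depth)")
        if self.exon_len < 2 * self.junction_anchor:
            raise ValueError("exons shorter than twice the junction anchor")
        for fam in self.families:
            if not 0 <= fam.mutation_rate <= 1:
                raise ValueError("mutation_rate must be in [0, 1]")
            if fam.exon_frac + fam.intron_frac > 1:
                raise ValueError(f"{fam.name}: placement fractions exceed 1")
            if fam.consensus_len < self.read_len:
                raise ValueError("repeat consensus shorter than read length")


def null_config(seed: int = 0) -> SimulationConfig:
    """Conditions with zero planted effects, for null calibration."""
    cfg = SimulationConfig(seed=seed, n_skip_up=0, n_skip_down=0,
                           n_skip_null=0, n_de_genes=0)
    for fam in cfg.families:
        fam.log2fc = 0.0
        fam.exon_frac, fam.intron_frac = 0.1, 0.4
        fam.strand_concordance = 0.5
    return cfg


@dataclass
class SyntheticDataset:
    """File paths of one generated dataset plus the in-memory truth ledger."""

    outdir: Path
    gtf: Path
    repeats: Path
    cells_dir: Path
    xlinks: Path
    alignment_fasta: Path | None
    groups_tsv: Path
    truth_json: Path
    truth: dict

    @property
    def groups(self) -> dict[str, str]:
        return dict(self.truth["groups"])


# ---------------------------------------------------------------------------


def _nb_draw(rng, mean: float, dispersion: float, size=None):
    """Negative binomial with var = mean + dispersion * mean^2."""
    if dispersion <= 0:
        return rng.poisson(mean, size=size)
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p, size=size)


def _gene_layout(cfg: SimulationConfig):
    """Deterministic gene geometry: id -> (strand placeholder, exon list)."""
    stride = (cfg.exons_per_gene * cfg.exon_len
              + (cfg.exons_per_gene - 1) * cfg.intron_len + cfg.intergenic_gap)
    genes = []
    for i in range(cfg.n_genes):
        off = 1000 + i * stride
        exons = [(off + k * (cfg.exon_len + cfg.intron_len),
                  off + k * (cfg.exon_len + cfg.intron_len) + cfg.exon_len)
                 for k in range(cfg.exons_per_gene)]
        genes.append((f"g{i:04d}", exons))
    return genes, stride


def _write_gtf(path: Path, genes, strands):
    with open(path, "w") as fh:
        for gid, exons in genes:
            strand = strands[gid]
            fh.write(f"{CHROM}\tsim\tgene\t{exons[0][0] + 1}\t{exons[-1][1]}"
                     f"\t.\t{strand}\t.\tgene_id \"{gid}\";\n")
            for k, (s, e) in enumerate(exons, 1):
                fh.write(f"{CHROM}\tsim\texon\t{s + 1}\t{e}\t.\t{strand}\t.\t"
                         f"gene_id \"{gid}\"; transcript_id \"{gid}.t1\"; "
                         f"exon_number \"{k}\";\n")


def _place_elements(rng, cfg: SimulationConfig, genes, strands, stride):
    """Place repeat element instances per family's genomic mixture."""
    elements = []       # dicts: name, family, class, start, end, strand, seq
    used: set[tuple[int, int]] = set()
    chrom_len = 1000 + cfg.n_genes * stride + 1000
    for fam in cfg.families:
        consensus = rng.choice(BASES, size=fam.consensus_len)
        elen = fam.consensus_len
        for _ in range(fam.n_elements):
            for _attempt in range(200):
                u = rng.random()
                gene = genes[int(rng.integers(len(genes)))]
                gid, exons = gene
                if u < fam.exon_frac:
                    s0, e0 = exons[int(rng.integers(len(exons)))]
                    lo, hi = s0, e0 - elen
                    in_gene = True
                elif u < fam.exon_frac + fam.intron_frac:
                    k = int(rng.integers(len(exons) - 1))
                    lo, hi = exons[k][1], exons[k + 1][0] - elen
                    in_gene = True
                else:
                    lo = exons[-1][1] + 50
                    hi = lo + cfg.intergenic_gap - 100 - elen
                    in_gene = False
                if hi <= lo:
                    continue
                start = int(rng.integers(lo, hi))
                if start + elen > chrom_len:
                    continue
                if (start, start + elen) in used:
                    continue
                used.add((start, start + elen))
                break
            else:
                raise RuntimeError("could not place repeat element")
            if in_gene:
                concord = rng.random() < fam.strand_concordance
                strand = strands[gid] if concord else (
                    "-" if strands[gid] == "+" else "+")
            else:
                strand = "+" if rng.random() < 0.5 else "-"
            seq = consensus.copy()
            mut = rng.random(elen) < fam.mutation_rate
            for i in np.flatnonzero(mut):
                choices = BASES[BASES != seq[i]]
                seq[i] = choices[int(rng.integers(3))]
            elements.append({
                "name": fam.name, "family": fam.family, "class": fam.class_,
                "start": start, "end": start + elen, "strand": strand,
                "seq": "".join(seq),
            })
        yield fam, "".join(consensus), [el for el in elements
                                        if el["name"] == fam.name]


def _write_repeat_table(path: Path, elements):
    with open(path, "w") as fh:
        fh.write("genoName\tgenoStart\tgenoEnd\tstrand\trepName\trepClass"
                 "\trepFamily\n")
        for el in sorted(elements, key=lambda e: (e["start"], e["name"])):
            fh.write(f"{CHROM}\t{el['start']}\t{el['end']}\t{el['strand']}\t"
                     f"{el['name']}\t{el['class']}\t{el['family']}\n")


def _sam_line(name, pos, cigar, cell):
    return (f"{name}\t0\t{CHROM}\t{pos + 1}\t50\t{cigar}\t*\t0\t0\t*\t*\t"
            f"NH:i:1\tRG:Z:{cell}\n")


def generate_dataset(cfg: SimulationConfig, outdir: str | Path
                     ) -> SyntheticDataset:
    """Generate annotation, repeats, per-cell SAM files, crosslinks and truth."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    outdir = Path(outdir)
    cells_dir = outdir / "cells"
    cells_dir.mkdir(parents=True, exist_ok=True)

    genes, stride = _gene_layout(cfg)
    strands = {gid: ("+" if rng.random() < 0.5 else "-") for gid, _ in genes}
    chrom_len = 1000 + cfg.n_genes * stride + 1000

    # --- role assignment ------------------------------------------------
    n_skip = cfg.n_skip_up + cfg.n_skip_down + cfg.n_skip_null
    picked = rng.choice(cfg.n_genes, size=n_skip + cfg.n_de_genes,
                        replace=False)
    skip_genes = picked[:n_skip]
    de_genes = picked[n_skip:]
    skip_events = []
    for j, gi in enumerate(skip_genes):
        gid, exons = genes[gi]
        kind = ("up" if j < cfg.n_skip_up else
                "down" if j < cfg.n_skip_up + cfg.n_skip_down else "null")
        exon_idx = int(rng.integers(1, cfg.exons_per_gene - 1))
        jstart = exons[exon_idx - 1][1]
        jend = exons[exon_idx + 1][0]
        lo, hi = cfg.base_skip_usage, cfg.base_skip_usage + cfg.delta_psi
        usage = {"up": (lo, hi), "down": (hi, lo),
                 "null": (cfg.null_skip_usage, cfg.null_skip_usage)}[kind]
        skip_events.append({
            "gene": gid, "kind": kind, "exon_index": exon_idx,
            "exon": [exons[exon_idx][0], exons[exon_idx][1]],
            "junction": f"{CHROM}:{jstart}-{jend}",
            "junction_start": jstart, "junction_end": jend,
            "strand": strands[gid],
            "usage_control": usage[0], "usage_mutant": usage[1],
        })
    skip_by_gene = {ev["gene"]: ev for ev in skip_events}
    de_lfc = {}
    for j, gi in enumerate(de_genes):
        gid, _ = genes[gi]
        de_lfc[gid] = float(np.log2(cfg.de_fold)) * (1 if j % 2 == 0 else -1)

    # per-gene base expression
    gene_mu = {gid: float(rng.gamma(2.0, cfg.gene_read_mean / 2.0))
               for gid, _ in genes}

    # --- repeats ---------------------------------------------------------
    all_elements = []
    fam_records = {}
    for fam, consensus, fam_elements in _place_elements(rng, cfg, genes,
                                                        strands, stride):
        fam_records[fam.name] = {"config": asdict(fam),
                                 "consensus": consensus,
                                 "elements": fam_elements}
        all_elements.extend(fam_elements)
    for el in all_elements:
        el["id"] = f"{el['name']}@{CHROM}:{el['start']}-{el['end']}"
        # constant expected count per element copy; the planted family fold
        # change multiplies it in the mutant group
        el["rate"] = float(cfg.repeat_read_mean)
    _write_repeat_table(outdir / "repeats.tsv", all_elements)
    _write_gtf(outdir / "annotation.gtf", genes, strands)

    # aligned FASTA of the expressed (planted-upregulated) family; point
    # mutations only, so the alignment is gap-free and rectangular
    planted = (max(cfg.families, key=lambda f: f.log2fc)
               if cfg.families else None)
    fasta_path = None
    if planted is not None and planted.log2fc > 0:
        fasta_path = outdir / f"{planted.name}_alignment.fasta"
        with open(fasta_path, "w") as fh:
            for el in fam_records[planted.name]["elements"]:
                eid = f"{el['name']}@{CHROM}:{el['start']}-{el['end']}"
                fh.write(f">{eid}\n{el['seq']}\n")

    # --- cells and reads -------------------------------------------------
    fam_by_name = {f.name: f for f in cfg.families}
    cells = ([f"ctrl{i + 1:02d}" for i in range(cfg.n_control)]
             + [f"mut{i + 1:02d}" for i in range(cfg.n_mutant)])
    groups = {c: (CONTROL if c.startswith("ctrl") else MUTANT) for c in cells}
    junction_truth: dict[str, dict[str, int]] = {}
    cell_totals: dict[str, int] = {}
    anchor = cfg.junction_anchor

    for cell in cells:
        mutant = groups[cell] == MUTANT
        lines = []
        nread = 0
        for gid, exons in genes:
            mu = gene_mu[gid]
            if mutant and gid in de_lfc:
                mu *= 2.0 ** de_lfc[gid]
            n = int(_nb_draw(rng, mu, cfg.gene_dispersion))
            if n == 0:
                continue
            n_junc = int(rng.binomial(n, cfg.splice_read_fraction))
            # junction menu: annotated neighbours, plus the planted skip
            juncs = [(exons[k][1], exons[k + 1][0])
                     for k in range(len(exons) - 1)]
            ev = skip_by_gene.get(gid)
            if ev is None:
                probs = np.full(len(juncs), 1.0 / len(juncs))
            else:
                u = ev["usage_mutant"] if mutant else ev["usage_control"]
                juncs = juncs + [(ev["junction_start"], ev["junction_end"])]
                probs = np.full(len(juncs), (1.0 - u) / (len(juncs) - 1))
                probs[-1] = u
            draws = rng.multinomial(n_junc, probs)
            for (js, je), k in zip(juncs, draws):
                if k == 0:
                    continue
                key = f"{CHROM}:{js}-{je}"
                junction_truth.setdefault(key, {})[cell] = \
                    junction_truth.get(key, {}).get(cell, 0) + int(k)
                cigar = f"{anchor}M{je - js}N{anchor}M"
                for _ in range(int(k)):
                    lines.append((js - anchor,
                                  _sam_line(f"{cell}.r{nread}", js - anchor,
                                            cigar, cell)))
                    nread += 1
            for _ in range(n - n_junc):
                s0, e0 = exons[int(rng.integers(len(exons)))]
                pos = int(rng.integers(s0, e0 - cfg.read_len + 1))
                lines.append((pos, _sam_line(f"{cell}.r{nread}", pos,
                                             f"{cfg.read_len}M", cell)))
                nread += 1
        for el in all_elements:
            fam_cfg = fam_by_name[el["name"]]
            lam = el["rate"] * (2.0 ** fam_cfg.log2fc if mutant else 1.0)
            k = int(rng.poisson(lam))
            for _ in range(k):
                pos = int(rng.integers(el["start"],
                                       el["end"] - cfg.read_len + 1))
                lines.append((pos, _sam_line(f"{cell}.r{nread}", pos,
                                             f"{cfg.read_len}M", cell)))
                nread += 1
        cell_totals[cell] = nread
        lines.sort(key=lambda x: x[0])
        with open(cells_dir / f"{cell}.sam", "w") as fh:
            fh.write("@HD\tVN:1.6\tSO:coordinate\n")
            fh.write(f"@SQ\tSN:{CHROM}\tLN:{chrom_len}\n")
            fh.write(f"@RG\tID:{cell}\tSM:{cell}\n")
            for _, ln in lines:
                fh.write(ln)

    # --- crosslinks -------------------------------------------------------
    xl: dict[tuple[int, str], int] = {}
    label_of = {"up": "enhanced", "down": "silenced", "null": "control"}
    for ev in skip_events:
        es, ee = ev["exon"]
        strand = ev["strand"]
        for (lo, hi, rate) in (
                (es - cfg.xlink_flank, es, cfg.xlink_base_rate),
                (es, ee, cfg.xlink_base_rate * (
                    cfg.xlink_enrichment if ev["kind"] == "up" else 1.0)),
                (ee, ee + cfg.xlink_flank, cfg.xlink_base_rate)):
            k = int(rng.poisson(rate * (hi - lo)))
            for pos in rng.integers(lo, hi, size=k):
                xl[(int(pos), strand)] = xl.get((int(pos), strand), 0) + 1
    with open(outdir / "xlinks.bed", "w") as fh:
        for (pos, strand), cnt in sorted(xl.items()):
            fh.write(f"{CHROM}\t{pos}\t{pos + 1}\txl\t{cnt}\t{strand}\n")

    with open(outdir / "groups.tsv", "w") as fh:
        fh.write("cell\tgroup\n")
        for c in cells:
            fh.write(f"{c}\t{groups[c]}\n")

    truth = {
        "chrom": CHROM,
        "chrom_len": chrom_len,
        "groups": groups,
        "cell_totals": cell_totals,
        "gene_strands": strands,
        "gene_mu": gene_mu,
        "de_genes": de_lfc,
        "skip_events": skip_events,
        "event_labels": {ev["junction"]: label_of[ev["kind"]]
                         for ev in skip_events},
        "junction_counts": junction_truth,
        "families": {name: {"config": rec["config"],
                            "consensus": rec["consensus"],
                            "element_ids": [
                                f"{el['name']}@{CHROM}:{el['start']}-{el['end']}"
                                for el in rec["elements"]],
                            "rates": {
                                f"{el['name']}@{CHROM}:{el['start']}-{el['end']}":
                                el["rate"] for el in rec["elements"]}}
                     for name, rec in fam_records.items()},
        "planted_family": (planted.name
                           if planted is not None and planted.log2fc > 0
                           else None),
        "xlink_enrichment": cfg.xlink_enrichment,
    }
    truth_json = outdir / "truth.json"
    truth_json.write_text(json.dumps(truth, indent=1, sort_keys=True))
    return SyntheticDataset(
        outdir=outdir, gtf=outdir / "annotation.gtf",
        repeats=outdir / "repeats.tsv", cells_dir=cells_dir,
        xlinks=outdir / "xlinks.bed", alignment_fasta=fasta_path,
        groups_tsv=outdir / "groups.tsv", truth_json=truth_json, truth=truth)


# ---------------------------------------------------------------------------
# FRET traces


@dataclass
class FretConfig:
    seed: int = 0
    n_control: int = 10
    n_mutant: int = 6
    n_points: int = 200
    dt_min: float = 1.0            # sampling interval, minutes
    peak_index: int = 120          # control activation peak (pre-GVBD)
    peak_sigma: float = 8.0        # samples
    gvbd_lag: int = 10             # GVBD this many samples after the peak
    baseline: float = 0.15
    noise_sd: float = 0.005        # channel noise, fraction of dynamic range
    walk_sd: float = 0.04          # mutant fluctuation scale
    background_T: float = 40.0
    background_D: float = 60.0

    def validate(self) -> None:
        if not 0 < self.peak_index < self.n_points:
            raise ValueError("peak index outside the trace")
        if self.noise_sd < 0 or self.walk_sd < 0:
            raise ValueError("noise scales must be >= 0")


def _control_archetype(cfg: FretConfig, peak: int) -> np.ndarray:
    i = np.arange(cfg.n_points)
    return cfg.baseline + (1.0 - cfg.baseline) * np.exp(
        -0.5 * ((i - peak) / cfg.peak_sigma) ** 2)


def _mutant_archetype(cfg: FretConfig, rng) -> np.ndarray:
    """Bounded mean-reverting walk: fluctuating activity, no activation peak."""
    x = np.empty(cfg.n_points)
    x[0] = 0.5
    for i in range(1, cfg.n_points):
        x[i] = x[i - 1] + 0.1 * (0.5 - x[i - 1]) + rng.normal(0, cfg.walk_sd)
        x[i] = min(max(x[i], 0.1), 0.9)
    return x


def generate_fret_traces(cfg: FretConfig, outdir: str | Path):
    """Write per-trace CSVs (t, T, D, dT, dD, event) plus a labels ledger.

    Channel construction: the donor is a slow linear ramp; the transmission
    channel is the activity archetype multiplied by the donor's rescaled
    shape, so that after the min/max normalization the ratio F equals the
    archetype up to one global scale factor and the planted peak position is
    preserved exactly in the noise-free limit.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t = np.arange(cfg.n_points) * cfg.dt_min
    ramp = 1.0 - np.arange(cfg.n_points) / (cfg.n_points - 1)   # 1 -> 0
    labels = {}
    paths = []
    names = ([f"fret_ctrl{i + 1:02d}" for i in range(cfg.n_control)]
             + [f"fret_mut{i + 1:02d}" for i in range(cfg.n_mutant)])
    for name in names:
        is_control = name.startswith("fret_ctrl")
        if is_control:
            jitter = int(rng.integers(-2, 3))
            peak = cfg.peak_index + jitter
            arche = _control_archetype(cfg, peak)
            gvbd_t = float(t[min(peak + cfg.gvbd_lag, cfg.n_points - 1)])
            labels[name] = {"archetype": "control", "peak_index": peak,
                            "gvbd_t": gvbd_t}
        else:
            arche = _mutant_archetype(cfg, rng)
            labels[name] = {"archetype": "mutant", "peak_index": None,
                            "gvbd_t": None}
        D = cfg.background_D + 80.0 * ramp + rng.normal(0, cfg.noise_sd * 80,
                                                        cfg.n_points)
        T = cfg.background_T + 120.0 * arche * ramp + rng.normal(
            0, cfg.noise_sd * 120, cfg.n_points)
        dT = np.full(cfg.n_points, cfg.background_T)
        dD = np.full(cfg.n_points, cfg.background_D)
        df = pd.DataFrame({"t": t, "T": T, "D": D, "dT": dT, "dD": dD})
        if labels[name]["gvbd_t"] is not None:
            ev = pd.Series(index=df.index, dtype=object)
            ev.iloc[int(np.argmin(np.abs(t - labels[name]["gvbd_t"])))] = "GVBD"
            df["event"] = ev
        path = outdir / f"{name}.csv"
        df.to_csv(path, index=False)
        paths.append(path)
    (outdir / "fret_labels.json").write_text(
        json.dumps(labels, indent=1, sort_keys=True))
    return paths, labels
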