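"""Synthetic cohort generator.

Produces complete toy cohorts — genome, per-platform capture regions,
MAF-like somatic mutation records, clinical/survival tables, and a truth
bundle — with the statistical structure the downstream stages assume:
multiple datasets of different sizes, per-gene nonsilent/synonymous
mutation probabilities, genome-wide substitutions drawn from SBS96
signature mixtures, proportional-hazards survival with planted prognostic
genes, and platform-specific capture masks that hide a tail of each gene's
CDS from exome-labelled datasets.

Layout of the toy genome: one contig per gene (padding + contiguous CDS +
padding, no introns) plus, when signature mixtures are simulated as
records, one dedicated ``sbs_source`` contig built by concatenating exactly
the trinucleotides each drawn substitution needs, so the SBS96 matrix
rebuilt from the emitted records reproduces the drawn counts exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .signatures import CHANNELS96

PAD = 60  # intergenic padding on each side of a gene's CDS
_BASES = np.array(list("ACGT"))

NONSILENT_CLASSES = ("Missense_Mutation", "Nonsense_Mutation", "Frame_Shift_Del",
                     "Splice_Site")
_NONSILENT_P = (0.85, 0.08, 0.04, 0.03)


@dataclass
class GeneModel:
    name: str
    cds_length: int
    p_nonsilent: float
    p_synonymous: float = 0.0


@dataclass
class SimulationConfig:
    """Knobs for one synthetic cohort.

    `platform_masks[d]` is the fraction of every gene's CDS (its 3' tail)
    missing from dataset d's capture regions; datasets with mask 0 are
    labelled WGS, others WES.  `exposure_truth` rows are signature mixing
    weights; samples are assigned to rows cyclically.
    """

    dataset_sizes: list[int]
    gene_models: list[GeneModel]
    signature_truth: np.ndarray | None = None       # k x 96
    exposure_truth: np.ndarray | None = None        # groups x k
    mutations_per_genome: float = 81.0              # mean total substitutions
    panel_truth: dict[str, float] = field(default_factory=dict)  # gene -> log HR
    baseline_hazard: float = 0.02
    censoring_rate: float = 0.3
    platform_masks: list[float] | None = None
    multi_hit_prob: float = 0.1
    seed: int = 0

    @property
    def n_datasets(self) -> int:
        return len(self.dataset_sizes)

    def validate(self) -> None:
        if not self.dataset_sizes or any(n < 1 for n in self.dataset_sizes):
            raise ValueError("dataset_sizes must all be >= 1")
        for g in self.gene_models:
            if not (0 <= g.p_nonsilent <= 1 and 0 <= g.p_synonymous <= 1):
                raise ValueError(f"gene {g.name}: probabilities must lie in [0, 1]")
            if g.cds_length < 3:
                raise ValueError(f"gene {g.name}: CDS shorter than one codon")
        if self.signature_truth is not None:
            sig = np.asarray(self.signature_truth, dtype=float)
            if sig.shape[1] != 96 or not np.allclose(sig.sum(axis=1), 1.0, atol=1e-9):
                raise ValueError("signature_truth rows must be length-96 and sum to 1")
            if self.exposure_truth is None:
                raise ValueError("exposure_truth required with signature_truth")
            if np.asarray(self.exposure_truth).shape[1] != sig.shape[0]:
                raise ValueError("exposure_truth/signature_truth dimension mismatch")
        if self.platform_masks is not None and len(self.platform_masks) != self.n_datasets:
            raise ValueError("platform_masks must have one entry per dataset")
        if not 0 <= self.censoring_rate <= 1:
            raise ValueError("censoring_rate must lie in [0, 1]")
        if self.baseline_hazard < 0:
            raise ValueError("baseline_hazard must be non-negative")
        names = {g.name for g in self.gene_models}
        for g in self.panel_truth:
            if g not in names:
                raise ValueError(f"panel gene {g} not in gene_models")


@dataclass
class TruthBundle:
    planted_panel: dict[str, float]
    planted_signatures: np.ndarray | None
    planted_exposures: pd.DataFrame | None   # sample x k mixing weights used
    gene_matrix: pd.DataFrame                # patients x genes nonsilent indicator
    multiplicity: pd.DataFrame               # patients x genes nonsilent record count
    sbs96_truth: pd.DataFrame | None         # the drawn channel counts per sample
    uncaptured_sites: dict[str, set]         # platform -> {(chrom, pos 1-based)}


@dataclass
class Cohort:
    records: pd.DataFrame
    clinical: pd.DataFrame
    genome: dict[str, str]
    capture: dict[str, pd.DataFrame]         # platform -> BED-like frame
    truth: TruthBundle
    config: SimulationConfig


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=n)])


def simulate_sbs96(signatures: np.ndarray, exposures: np.ndarray,
                   totals, seed: int = 0) -> pd.DataFrame:
    """Draw per-sample SBS96 counts from a signature mixture.

    Each sample's 96-vector is a multinomial draw of its total count with
    probabilities equal to its (row-normalized) exposure-weighted mixture of
    signature probability vectors.
    """
    sig = np.asarray(signatures, dtype=float)
    expo = np.atleast_2d(np.asarray(exposures, dtype=float))
    if sig.shape[0] != expo.shape[1]:
        raise ValueError("exposures columns must match number of signatures")
    totals = np.atleast_1d(np.asarray(totals))
    if (totals < 0).any():
        raise ValueError("totals must be >= 0")
    if expo.shape[0] != totals.shape[0]:
        raise ValueError("one exposure row per sample required")
    rowsum = expo.sum(axis=1, keepdims=True)
    if (rowsum <= 0).any():
        raise ValueError("exposure rows must be normalizable (positive sums)")
    probs = (expo / rowsum) @ sig
    rng = np.random.default_rng(seed)
    out = np.zeros((len(totals), 96), dtype=int)
    for i, (t, p) in enumerate(zip(totals, probs)):
        if t > 0:
            out[i] = rng.multinomial(int(t), p / p.sum())
    return pd.DataFrame(out, columns=list(CHANNELS96))


def simulate_survival(gene_matrix: pd.DataFrame, panel_truth: dict[str, float],
                      baseline_hazard: float, censoring_rate: float,
                      seed: int = 0) -> pd.DataFrame:
    """Proportional-hazards event times with planted per-gene effects.

    Event times are exponential with hazard
    ``baseline * exp(sum of log-HRs over the patient's mutated panel genes)``;
    censoring is an independent exponential whose rate is tuned so that the
    expected censored fraction matches ``censoring_rate`` for a baseline
    patient (``censoring_rate`` 1 censors everything).
    """
    if baseline_hazard <= 0:
        raise ValueError("baseline_hazard must be positive")
    missing = [g for g in panel_truth if g not in gene_matrix.columns]
    if missing:
        raise ValueError(f"panel genes absent from matrix: {missing}")
    rng = np.random.default_rng(seed)
    n = len(gene_matrix)
    lp = np.zeros(n)
    for g, beta in panel_truth.items():
        lp += beta * gene_matrix[g].to_numpy(dtype=float)
    hazard = baseline_hazard * np.exp(lp)
    t_event = rng.exponential(1.0 / hazard)
    if censoring_rate >= 1.0:
        time, event = rng.exponential(1.0 / baseline_hazard, size=n), np.zeros(n, dtype=int)
    elif censoring_rate <= 0.0:
        time, event = t_event, np.ones(n, dtype=int)
    else:
        lam_c = baseline_hazard * censoring_rate / (1.0 - censoring_rate)
        t_cens = rng.exponential(1.0 / lam_c, size=n)
        event = (t_event <= t_cens).astype(int)
        time = np.minimum(t_event, t_cens)
    return pd.DataFrame({"os_time": time, "os_event": event}, index=gene_matrix.index)


def _draw_clinical(rng: np.random.Generator, sample_ids, dataset_ids,
                   seq_types, platforms) -> pd.DataFrame:
    n = len(sample_ids)
    age = np.clip(np.round(rng.normal(62, 8, size=n)), 30, 90).astype(int)
    stage = rng.choice(["I", "II", "III", "IV"], size=n, p=[0.15, 0.3, 0.4, 0.15])
    return pd.DataFrame({
        "sample_id": sample_ids,
        "dataset_id": dataset_ids,
        "age": age,
        "sex": rng.choice(["male", "female"], size=n, p=[0.8, 0.2]),
        "smoking": rng.choice(["yes", "no"], size=n, p=[0.55, 0.45]),
        "drinking": rng.choice(["yes", "no"], size=n, p=[0.55, 0.45]),
        "stage": stage,
        "location": rng.choice(["upper", "middle", "lower"], size=n, p=[0.2, 0.5, 0.3]),
        "seq_type": seq_types,
        "platform": platforms,
    }).set_index("sample_id")


def simulate_cohort(config: SimulationConfig) -> Cohort:
    """Generate a full synthetic cohort per the configuration.

    Every emitted record's ref allele matches the emitted genome at its
    position; records at capture-masked sites are dropped from WES-labelled
    datasets (and retained for WGS ones), and the truth gene matrix reflects
    what was actually emitted.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    genes = config.gene_models
    gene_names = [g.name for g in genes]

    # genome: one contig per gene, CDS at [PAD, PAD + L) (0-based)
    genome = {g.name: _random_seq(rng, PAD + g.cds_length + PAD) for g in genes}

    masks = config.platform_masks or [0.0] * config.n_datasets
    dataset_ids = [f"ds{d}" for d in range(config.n_datasets)]
    seq_type = {ds: ("WES" if masks[d] > 0 else "WGS") for d, ds in enumerate(dataset_ids)}
    platform = {ds: (f"platform_{d}" if masks[d] > 0 else "WGS") for d, ds in enumerate(dataset_ids)}

    # capture regions per platform: the captured prefix of each gene's CDS
    capture: dict[str, pd.DataFrame] = {}
    captured_len: dict[str, dict[str, int]] = {}
    uncaptured_sites: dict[str, set] = {}
    for d, ds in enumerate(dataset_ids):
        plat = platform[ds]
        if plat in capture:
            continue
        frac = masks[d]
        rows, clens = [], {}
        for g in genes:
            keep = g.cds_length if frac == 0 else int(np.floor(g.cds_length * (1 - frac)))
            clens[g.name] = keep
            if keep > 0:
                rows.append((g.name, PAD, PAD + keep))
        capture[plat] = pd.DataFrame(rows, columns=["chrom", "start", "end"])
        captured_len[plat] = clens
        uncaptured_sites[plat] = set()

    sample_ids, sample_ds = [], []
    for ds, n in zip(dataset_ids, config.dataset_sizes):
        for i in range(n):
            sample_ids.append(f"{ds}_P{i:04d}")
            sample_ds.append(ds)
    n_samples = len(sample_ids)

    indicator = pd.DataFrame(0, index=pd.Index(sample_ids, name="sample_id"),
                             columns=gene_names, dtype=int)
    multiplicity = indicator.copy()

    rec_rows: list[tuple] = []

    def emit(sample, ds, gene, pos0, vclass, vtype="SNP", ref=None, alt=None):
        seq = genome[gene]
        if ref is None:
            ref = seq[pos0]
            alt = str(rng.choice([b for b in "ACGT" if b != ref]))
        rec_rows.append((sample, ds, gene, pos0 + 1, ref, alt, gene,
                         f"TX_{gene}", vclass, vtype))

    # per-gene Bernoulli mutations within the CDS
    for si, (sample, ds) in enumerate(zip(sample_ids, sample_ds)):
        plat = platform[ds]
        clens = captured_len[plat]
        for g in genes:
            visible_len = clens[g.name]
            n_ns = 0
            if g.p_nonsilent > 0 and rng.random() < g.p_nonsilent:
                n_ns = 1 + (rng.random() < config.multi_hit_prob)
            for _ in range(n_ns):
                pos0 = PAD + int(rng.integers(0, g.cds_length))
                vclass = str(rng.choice(NONSILENT_CLASSES, p=_NONSILENT_P))
                in_capture = (pos0 - PAD) < visible_len
                if seq_type[ds] == "WES" and not in_capture:
                    uncaptured_sites[plat].add((g.name, pos0 + 1))
                    continue  # invisible to this exome platform
                if not in_capture:
                    uncaptured_sites[plat].add((g.name, pos0 + 1))
                vtype = "DEL" if vclass == "Frame_Shift_Del" else "SNP"
                if vtype == "DEL":
                    seq = genome[g.name]
                    if pos0 + 2 >= len(seq):
                        pos0 -= 2
                    emit(sample, ds, g.name, pos0, vclass, "DEL",
                         ref=seq[pos0:pos0 + 2], alt=seq[pos0])
                else:
                    emit(sample, ds, g.name, pos0, vclass)
                indicator.iloc[si, indicator.columns.get_loc(g.name)] = 1
                multiplicity.iloc[si, multiplicity.columns.get_loc(g.name)] += 1
            if g.p_synonymous > 0 and rng.random() < g.p_synonymous:
                pos0 = PAD + int(rng.integers(0, g.cds_length))
                if (pos0 - PAD) < visible_len or seq_type[ds] == "WGS":
                    emit(sample, ds, g.name, pos0, "Silent")

    # genome-wide substitutions from the planted signature mixture
    sbs_truth = None
    expo_used = None
    if config.signature_truth is not None:
        sig = np.asarray(config.signature_truth, dtype=float)
        groups = np.arange(n_samples) % np.asarray(config.exposure_truth).shape[0]
        expo = np.asarray(config.exposure_truth, dtype=float)[groups]
        totals = rng.poisson(config.mutations_per_genome, size=n_samples)
        sbs_truth = simulate_sbs96(sig, expo, totals,
                                   seed=int(rng.integers(0, 2**31 - 1)))
        sbs_truth.index = pd.Index(sample_ids, name="sample_id")
        expo_used = pd.DataFrame(expo, index=sbs_truth.index,
                                 columns=[f"sig{i+1}" for i in range(sig.shape[0])])
        # build the context-farm contig: exact trinucleotide per drawn record
        channel_demand = sbs_truth.sum(axis=0)
        farm_parts, farm_pos = [], {}
        cursor = 0
        for ch in CHANNELS96:
            need = int(channel_demand[ch])
            if need == 0:
                continue
            left, mid, right = ch[0], ch[2], ch[6]
            farm_pos[ch] = [cursor + 3 * i + 1 for i in range(need)]  # 0-based centers
            farm_parts.append((left + mid + right) * need)
            cursor += 3 * need
        genome["sbs_source"] = "".join(farm_parts)
        for si, sample in enumerate(sample_ids):
            counts = sbs_truth.iloc[si]
            for ch in CHANNELS96:
                c = int(counts[ch])
                for _ in range(c):
                    pos0 = farm_pos[ch].pop()
                    ref, alt = ch[2], ch[4]
                    rec_rows.append((sample, sample_ds[si], "sbs_source", pos0 + 1,
                                     ref, alt, "IGR", "NA", "IGR", "SNP"))

    records = pd.DataFrame(rec_rows, columns=[
        "Tumor_Sample_Barcode", "Dataset", "Chromosome", "Start_Position",
        "Reference_Allele", "Tumor_Seq_Allele2", "Hugo_Symbol", "Transcript_ID",
        "Variant_Classification", "Variant_Type"])

    clinical = _draw_clinical(rng, sample_ids, sample_ds,
                              [seq_type[d] for d in sample_ds],
                              [platform[d] for d in sample_ds])
    surv = simulate_survival(indicator, config.panel_truth, config.baseline_hazard,
                             config.censoring_rate,
                             seed=int(rng.integers(0, 2**31 - 1)))
    clinical = clinical.join(surv)

    truth = TruthBundle(
        planted_panel=dict(config.panel_truth),
        planted_signatures=(None if config.signature_truth is None
                            else np.asarray(config.signature_truth, dtype=float)),
        planted_exposures=expo_used,
        gene_matrix=indicator,
        multiplicity=multiplicity,
        sbs96_truth=sbs_truth,
        uncaptured_sites=uncaptured_sites,
    )
    return Cohort(records=records, clinical=clinical.reset_index(), genome=genome,
                  capture=capture, truth=truth, config=config)


# --- writers ---------------------------------------------------------------

def write_cohort(cohort: Cohort, out_dir) -> dict[str, str]:
    """Write MAF-like TSV, clinical TSV, FASTA, per-platform BED, truth JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    maf = out / "mutations.maf.tsv"
    cohort.records.to_csv(maf, sep="\t", index=False)
    paths["maf"] = str(maf)
    clin = out / "clinical.tsv"
    cohort.clinical.to_csv(clin, sep="\t", index=False)
    paths["clinical"] = str(clin)
    fa = out / "genome.fa"
    with open(fa, "w") as fh:
        for name, seq in cohort.genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i:i + 70] + "\n")
    paths["genome"] = str(fa)
    for plat, bed in cohort.capture.items():
        p = out / f"capture_{plat}.bed"
        bed.to_csv(p, sep="\t", index=False, header=False)
        paths[f"bed_{plat}"] = str(p)
    truth = out / "truth.json"
    with open(truth, "w") as fh:
        json.dump({
            "planted_panel": cohort.truth.planted_panel,
            "uncaptured_sites": {k: sorted(map(list, v))
                                 for k, v in cohort.truth.uncaptured_sites.items()},
            "gene_matrix": cohort.truth.gene_matrix.to_dict(orient="index"),
        }, fh)
    paths["truth"] = str(truth)
    return paths


def simulate_survival_cohort(gene_probs: dict[str, float], n: int,
                             panel_truth: dict[str, float],
                             baseline_hazard: float = 0.02,
                             censoring_rate: float = 0.3,
                             n_datasets: int = 1,
                             seed: int = 0) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Vectorized gene-matrix + clinical/survival cohort (no record emission).

    The record-level generator is exact but per-record; panel-recovery
    studies need thousands of patients by hundreds of genes, for which only
    the binary nonsilent indicator matters.  Draws each gene's indicator as
    an independent Bernoulli, survival from the proportional-hazards model,
    and the standard clinical covariates.
    """
    rng = np.random.default_rng(seed)
    genes = list(gene_probs)
    P = np.array([gene_probs[g] for g in genes])
    if ((P < 0) | (P > 1)).any():
        raise ValueError("gene probabilities must lie in [0, 1]")
    ids = [f"ds{i % n_datasets}_P{i:05d}" for i in range(n)]
    X = (rng.random((n, len(genes))) < P[None, :]).astype(int)
    gm = pd.DataFrame(X, index=pd.Index(ids, name="sample_id"), columns=genes)
    ds = [f"ds{i % n_datasets}" for i in range(n)]
    clinical = _draw_clinical(rng, ids, ds, ["WGS"] * n, ["WGS"] * n)
    surv = simulate_survival(gm, panel_truth, baseline_hazard, censoring_rate,
                             seed=int(rng.integers(0, 2**31 - 1)))
    clinical = clinical.join(surv)
    return gm, clinical.reset_index()


def mixture_exposures(k: int, n: int, seed: int = 0, base: float = 0.8,
                      decay: float = 0.55, floor: float = 0.15) -> np.ndarray:
    """Per-sample signature mixing weights with unequal prevalence.

    Dirichlet draws whose concentration decays geometrically across
    signatures (alpha_i = max(base * decay^i, floor)), mirroring real
    cohorts where a few mutational processes dominate most genomes.  The
    asymmetry makes low-rank consensus clustering deterministic, which is
    the regime in which cophenetic rank selection is well posed.
    """
    rng = np.random.default_rng(seed)
    alpha = np.maximum(base * decay ** np.arange(k), floor)
    return rng.dirichlet(alpha, size=n)


def random_signatures(k: int, seed: int = 0, concentration: float = 0.3,
                      sparsity: float = 0.75) -> np.ndarray:
    """Draw k well-separated synthetic SBS96 signature profiles.

    Each signature concentrates its mass on a random subset of channels
    (Dirichlet over the active set), which keeps pairwise cosine similarity
    low — the regime in which NMF rank selection is well posed.
    """
    rng = np.random.default_rng(seed)
    sigs = np.zeros((k, 96))
    n_active = max(6, int(96 * (1 - sparsity)))
    for i in range(k):
        active = rng.choice(96, size=n_active, replace=False)
        sigs[i, active] = rng.dirichlet(np.full(n_active, concentration))
    return sigs
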