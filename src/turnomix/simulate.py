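"""Synthetic multi-omic data with known ground truth.

Emulates a 2-day heavy-pulse SILAC experiment in three genotypes
(isogenic reference plus two mutants) under two media conditions with four
biological replicates, together with a class-structured lipidome measured
in technical duplicate against spiked internal standards, a transcript
feature matrix, and a bait-pulldown interactome with planted client
proteins.

Generative model
----------------
Protein turnover is first-order at steady state: over a pulse of length
t_s the light channel of a peptide decays as e^(-k t_s) and the heavy
channel accumulates as 1 - e^(-k t_s), so the heavy-to-light ratio is
psi = e^(k t_s) - 1 (> 0 always). Per-peptide channel intensities are

    abundance x ionization factor x channel fraction x lognormal noise,

where the two channels of one record share a common-mode noise component
(fraction ``channel_correlation`` of the log-variance): sample handling and
ionization drift act on both isotope channels of the same peptide equally
and partially cancel in the ratio. Records whose total intensity falls
below the missingness floor are emitted as missing (intensity-dependent,
MNAR).

Planted clients are interactors whose per-sample half-life profile shares
a latent factor with designated lipid and transcript features, with
opposite sign, so that the downstream correlation stage can recover them.

All randomness flows from ``SimulationSpec.seed`` through named child
streams, so each generator is reproducible standalone and mutually
consistent (the latent factor is shared across omic layers).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .io import ExperimentDesign, ValidationError, log_stage

__all__ = [
    "SimulationSpec",
    "protein_truth",
    "latent_factor",
    "simulate_turnover",
    "simulate_turnover_arrays",
    "simulate_lipidome",
    "simulate_transcriptome",
    "simulate_interactome",
    "simulate_all",
]

_STREAMS = ("truth", "latent", "turnover", "lipidome", "transcriptome",
            "interactome")

LIPID_CLASSES = ("TAG", "CE", "DAG", "PC", "PE", "SM")


@dataclass(frozen=True)
class SimulationSpec:
    """Parameters of the synthetic study; defaults are the study conditions.

    Effect sizes: ``half_life_fold_change`` multiplies mutant half-lives of
    affected proteins (2x = clearly prolonged); ``lipid_fold_changes`` maps
    lipid classes to the mutant fold change of their species (0.5 = depleted
    storage lipids). ``intensity_sd`` is the lognormal sigma of each channel
    intensity, with correlation ``channel_correlation`` between the two
    channels of one record.
    """

    design: ExperimentDesign = field(default_factory=ExperimentDesign)
    n_proteins: int = 200
    peptides_per_protein: int = 6
    n_lipids: int = 120
    n_transcripts: int = 400
    n_interactors: int = 20
    n_planted_clients: int = 5
    n_decoy_interactome: int = 60
    n_contaminants: int = 5
    # kinetics
    median_half_life_days: float = 2.5
    log_half_life_sd: float = 0.5
    frac_prolonged: float = 0.15
    frac_shortened: float = 0.03
    half_life_fold_change: float = 2.0
    bio_sd: float = 0.05
    # intensity noise model
    intensity_sd: float = 0.2
    channel_correlation: float = 0.5
    base_abundance: float = 2.0e5
    log_abundance_sd: float = 1.0
    ionization_sd: float = 0.5
    missingness_floor: float = 1000.0
    # lipidome
    lipid_fold_changes: tuple = (("TAG", 0.25), ("CE", 0.25))
    lipid_sd: float = 0.2
    # residual error specific to the internal-standard measurement itself;
    # extraction and instrument drift are shared with the analytes of the
    # run (the run scale) and cancel under normalization, leaving only
    # ion-counting noise on the spiked standard
    is_sd: float = 0.05
    run_scale_sd: float = 0.3
    n_technical_runs: int = 2
    lipid_base_intensity: float = 1.0e5
    # transcriptome
    transcript_sd: float = 0.3
    frac_transcripts_affected: float = 0.1
    transcript_fold_change: float = 2.0
    # latent-factor coupling of planted clients to partner features; the
    # shared genotype effect (prolonged client vs depleted partner) carries
    # most of the correlation, the latent factor aligns replicate-level
    # deviations without drowning the group effect
    client_loading: float = 0.15
    partner_loading: float = 0.5
    partners_per_client: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_proteins", "n_lipids", "n_transcripts",
                     "n_interactors", "n_planted_clients",
                     "n_decoy_interactome", "n_contaminants"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        for name in ("intensity_sd", "bio_sd", "lipid_sd", "transcript_sd",
                     "ionization_sd", "log_half_life_sd", "run_scale_sd"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if self.n_planted_clients > self.n_interactors:
            raise ValidationError(
                "n_planted_clients cannot exceed n_interactors")
        if not (0 <= self.channel_correlation <= 1):
            raise ValidationError("channel_correlation must lie in [0, 1]")
        if self.peptides_per_protein < 1 or self.n_technical_runs < 1:
            raise ValidationError("need >= 1 peptide and >= 1 technical run")
        if self.median_half_life_days <= 0 or self.half_life_fold_change <= 0:
            raise ValidationError("half-life parameters must be > 0")

    def with_(self, **kwargs) -> "SimulationSpec":
        return replace(self, **kwargs)


def _rng(spec: SimulationSpec, stream: str) -> np.random.Generator:
    """Named child stream of the master seed (stable order across calls)."""
    children = np.random.SeedSequence(spec.seed).spawn(len(_STREAMS))
    return np.random.default_rng(children[_STREAMS.index(stream)])


# ---------------------------------------------------------------------------
# Shared ground truth
# ---------------------------------------------------------------------------

def latent_factor(spec: SimulationSpec) -> pd.Series:
    """Per-sample latent factor z ~ N(0,1) shared across omic layers."""
    samples = spec.design.sample_ids()
    z = _rng(spec, "latent").standard_normal(len(samples))
    return pd.Series(z, index=samples, name="z")


def protein_truth(spec: SimulationSpec) -> pd.DataFrame:
    """Ground truth per protein: kinetics, effect class, interactome role.

    Columns include one ``k_<genotype>_<condition>`` degradation rate
    (per day) per design cell; ``effect_class`` in {null, prolonged,
    shortened}; ``affected_conditions`` in {none, both, CM-like, GS-like
    labels}; ``is_interactor``/``is_planted_client``/``is_contaminant``.
    Planted clients are prolonged in both conditions; decoy interactors are
    drawn from null proteins.
    """
    rng = _rng(spec, "truth")
    design = spec.design
    n = spec.n_proteins
    ids = [f"P{i:04d}" for i in range(n)]

    t_base = spec.median_half_life_days * np.exp(
        rng.normal(0.0, spec.log_half_life_sd, n))
    k_base = np.log(2.0) / t_base

    effect = np.full(n, "null", dtype=object)
    n_pro = int(round(spec.frac_prolonged * n))
    n_sho = int(round(spec.frac_shortened * n))
    order = rng.permutation(n)
    pro_idx = order[:n_pro]
    sho_idx = order[n_pro:n_pro + n_sho]
    effect[pro_idx] = "prolonged"
    effect[sho_idx] = "shortened"

    cond_labels = ["both"] + list(design.conditions)
    affected = np.full(n, "none", dtype=object)
    probs = [0.5] + [0.5 / len(design.conditions)] * len(design.conditions)
    affected_draw = rng.choice(cond_labels, size=n, p=probs)
    changed = effect != "null"
    affected[changed] = affected_draw[changed]

    # planted clients: prolonged in both conditions, always interactors
    planted = np.zeros(n, dtype=bool)
    if spec.n_planted_clients:
        client_idx = pro_idx[: spec.n_planted_clients]
        if len(client_idx) < spec.n_planted_clients:
            raise ValidationError(
                "frac_prolonged too small to host the planted clients")
        planted[client_idx] = True
        affected[client_idx] = "both"

    interactor = planted.copy()
    n_decoy_int = spec.n_interactors - spec.n_planted_clients
    null_pool = np.flatnonzero(effect == "null")
    if n_decoy_int > len(null_pool):
        raise ValidationError("not enough null proteins for decoy interactors")
    interactor[rng.choice(null_pool, size=n_decoy_int, replace=False)] = True

    truth = pd.DataFrame({
        "protein_id": ids,
        "effect_class": effect,
        "affected_conditions": affected,
        "is_interactor": interactor,
        "is_planted_client": planted,
        "n_peptides": spec.peptides_per_protein,
        "base_half_life_days": t_base,
    })
    fold = spec.half_life_fold_change
    for c in design.conditions:
        for g in design.genotypes:
            k = k_base.copy()
            mutant = g != design.reference_genotype
            hit = changed & ((affected == "both") | (affected == c))
            if mutant:
                k[hit & (effect == "prolonged")] /= fold
                k[hit & (effect == "shortened")] *= fold
            truth[f"k_{g}_{c}"] = k
    return truth


# ---------------------------------------------------------------------------
# Turnover (peptide-level SILAC)
# ---------------------------------------------------------------------------

def _correlated_lognormal(rng, sd: float, rho: float, shape) -> tuple:
    """Two lognormal noise fields with correlated logs (common + specific)."""
    if sd == 0:
        ones = np.ones(shape)
        return ones, ones.copy()
    common = rng.normal(0.0, sd * np.sqrt(rho), shape)
    spec_l = rng.normal(0.0, sd * np.sqrt(1.0 - rho), shape)
    spec_h = rng.normal(0.0, sd * np.sqrt(1.0 - rho), shape)
    return np.exp(common + spec_l), np.exp(common + spec_h)


def simulate_turnover_arrays(spec: SimulationSpec,
                             truth: pd.DataFrame | None = None) -> dict:
    """Array kernel behind :func:`simulate_turnover`.

    Returns a dict with ``light``/``heavy`` intensity arrays of shape
    (n_proteins, n_peptides, n_samples), the per-record ``missing`` mask
    (total intensity below the floor), sample metadata, and the per-sample
    true half-lives (n_proteins, n_samples). Contaminant decoys are not
    included here; :func:`simulate_turnover` appends them to the table.
    """
    if truth is None:
        truth = protein_truth(spec)
    rng = _rng(spec, "turnover")
    design = spec.design
    samples = design.sample_ids()
    n_s = len(samples)
    n_p = spec.n_proteins
    n_pep = spec.peptides_per_protein
    ts = design.pulse_time_days

    k_cell = np.empty((n_p, n_s))
    for j, s in enumerate(samples):
        g, c, _r = s.rsplit("_", 2)
        k_cell[:, j] = truth[f"k_{g}_{c}"].to_numpy()

    z = latent_factor(spec).to_numpy()
    planted = truth["is_planted_client"].to_numpy(bool)
    ln_k = np.log(k_cell)
    if spec.bio_sd > 0:
        ln_k = ln_k + rng.normal(0.0, spec.bio_sd, (n_p, n_s))
    # latent factor raises the half-life (lowers k) of planted clients
    ln_k[planted] = ln_k[planted] - spec.client_loading * z[None, :]
    k_sample = np.exp(ln_k)

    light_frac = np.exp(-k_sample * ts)
    heavy_frac = 1.0 - light_frac

    abundance = spec.base_abundance * np.exp(
        rng.normal(0.0, spec.log_abundance_sd, n_p))
    ionization = np.exp(rng.normal(0.0, spec.ionization_sd, (n_p, n_pep)))
    base = abundance[:, None, None] * ionization[:, :, None]

    noise_l, noise_h = _correlated_lognormal(
        rng, spec.intensity_sd, spec.channel_correlation, (n_p, n_pep, n_s))
    light = base * light_frac[:, None, :] * noise_l
    heavy = base * heavy_frac[:, None, :] * noise_h
    missing = (light + heavy) < spec.missingness_floor

    t_true = np.log(2.0) / k_sample
    return {"light": light, "heavy": heavy, "missing": missing,
            "samples": samples, "truth": truth, "true_half_life": t_true}


def simulate_turnover(spec: SimulationSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Long-format peptide table plus protein ground truth.

    Records below the missingness floor are omitted from the table (and
    counted in the log); contaminant decoy proteins are appended and
    flagged.
    """
    arrays = simulate_turnover_arrays(spec)
    truth = arrays["truth"]
    design = spec.design
    samples = arrays["samples"]
    n_p, n_pep, n_s = arrays["light"].shape

    prot = np.repeat(truth["protein_id"].to_numpy(), n_pep * n_s)
    pep = np.tile(np.repeat([f"PEP{j:02d}" for j in range(n_pep)], n_s), n_p)
    pep = np.char.add(np.char.add(prot.astype(str), "_"), pep.astype(str))
    samp = np.tile(np.asarray(samples), n_p * n_pep)

    table = pd.DataFrame({
        "protein_id": prot,
        "peptide_seq": pep,
        "sample_id": samp,
        "light_intensity": arrays["light"].ravel(),
        "heavy_intensity": arrays["heavy"].ravel(),
        "is_contaminant": False,
    })
    keep = ~arrays["missing"].ravel()
    n_missing = int((~keep).sum())
    table = table.loc[keep]

    if spec.n_contaminants:
        rng = _rng(spec, "turnover")  # fresh stream; contaminant content is decor
        rows = []
        for i in range(spec.n_contaminants):
            pid = f"CONTAM{i:02d}"
            for s in samples:
                inten = spec.base_abundance * rng.lognormal(0.0, 0.5)
                rows.append((pid, f"{pid}_PEP00", s, inten * 0.5, inten * 0.5, True))
        contam = pd.DataFrame(rows, columns=["protein_id", "peptide_seq",
                                             "sample_id", "light_intensity",
                                             "heavy_intensity", "is_contaminant"])
        table = pd.concat([table, contam], ignore_index=True)

    meta = table["sample_id"].str.rsplit("_", n=2, expand=True)
    table["genotype"] = meta[0]
    table["condition"] = meta[1]
    table["replicate"] = meta[2].str.lstrip("r").astype(int)
    table = table[["protein_id", "peptide_seq", "sample_id", "genotype",
                   "condition", "replicate", "light_intensity",
                   "heavy_intensity", "is_contaminant"]].reset_index(drop=True)
    log_stage("simulate_turnover", n_p * n_pep * n_s, len(table),
              {"below_missingness_floor": n_missing}, seed=spec.seed)
    return table, truth


# ---------------------------------------------------------------------------
# Lipidome
# ---------------------------------------------------------------------------

def lipid_species_table(spec: SimulationSpec) -> pd.DataFrame:
    """Deterministic species -> class/internal-standard assignment."""
    classes = [LIPID_CLASSES[i % len(LIPID_CLASSES)] for i in range(spec.n_lipids)]
    species = [f"{c}_{i:03d}" for i, c in enumerate(classes)]
    return pd.DataFrame({
        "species": species,
        "lipid_class": classes,
        "internal_standard_id": [f"IS_{c}" for c in classes],
    })


def _partner_lipids(spec: SimulationSpec) -> dict[int, list[str]]:
    """Planted-client -> lipid partner species (taken from affected classes)."""
    sp = lipid_species_table(spec)
    affected_classes = [c for c, _f in spec.lipid_fold_changes]
    pool = sp.loc[sp["lipid_class"].isin(affected_classes), "species"].tolist()
    need = spec.n_planted_clients * spec.partners_per_client
    if need > len(pool):
        raise ValidationError("not enough species in affected classes for partners")
    return {i: pool[i * spec.partners_per_client:(i + 1) * spec.partners_per_client]
            for i in range(spec.n_planted_clients)}


def simulate_lipidome(spec: SimulationSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Long-format lipid table (with internal standards) plus species truth.

    Internal standards are constant across runs up to measurement noise;
    every species in a class designated by ``lipid_fold_changes`` is
    multiplied by the class fold change in mutant samples. Each biological
    sample is measured in ``n_technical_runs`` runs whose global scale
    factor cancels under internal-standard normalization.
    """
    rng = _rng(spec, "lipidome")
    design = spec.design
    samples = design.sample_ids()
    z = latent_factor(spec).to_numpy()
    sp = lipid_species_table(spec)
    fold_of = dict(spec.lipid_fold_changes)
    partners = _partner_lipids(spec)
    partner_species = {s for lst in partners.values() for s in lst}

    n_sp = len(sp)
    n_s = len(samples)
    n_runs = spec.n_technical_runs
    fold = sp["lipid_class"].map(lambda c: fold_of.get(c, 1.0)).to_numpy(float)
    is_partner = sp["species"].isin(partner_species).to_numpy(bool)
    mutant = np.array([s.rsplit("_", 2)[0] != design.reference_genotype
                       for s in samples])

    base = spec.lipid_base_intensity * np.exp(rng.normal(0.0, 1.0, n_sp))
    # species x sample biological level: class fold change in mutants plus
    # the shared latent factor on client-partner species (negative sign)
    level = base[:, None] * np.where(mutant[None, :], fold[:, None], 1.0)
    level = level * np.where(is_partner[:, None],
                             np.exp(-spec.partner_loading * z[None, :]), 1.0)

    scale = np.exp(rng.normal(0.0, spec.run_scale_sd, (n_s, n_runs)))
    noise = np.exp(rng.normal(0.0, spec.lipid_sd, (n_sp, n_s, n_runs)))
    inten = level[:, :, None] * scale[None, :, :] * noise

    n_cls = len(LIPID_CLASSES)
    is_noise = np.exp(rng.normal(0.0, spec.is_sd, (n_cls, n_s, n_runs)))
    is_inten = spec.lipid_base_intensity * scale[None, :, :] * is_noise

    geno = np.array([s.rsplit("_", 2)[0] for s in samples])
    cond = np.array([s.rsplit("_", 2)[1] for s in samples])
    repl = np.array([int(s.rsplit("_", 2)[2].lstrip("r")) for s in samples])
    run_ids = np.array([[f"{s}_run{r + 1}" for r in range(n_runs)]
                        for s in samples])

    def melt(species, classes, std_ids, values, is_std):
        n_f = len(species)
        return pd.DataFrame({
            "species": np.repeat(species, n_s * n_runs),
            "lipid_class": np.repeat(classes, n_s * n_runs),
            "internal_standard_id": np.repeat(std_ids, n_s * n_runs),
            "run_id": np.tile(run_ids.ravel(), n_f),
            "sample_id": np.tile(np.repeat(samples, n_runs), n_f),
            "genotype": np.tile(np.repeat(geno, n_runs), n_f),
            "condition": np.tile(np.repeat(cond, n_runs), n_f),
            "replicate": np.tile(np.repeat(repl, n_runs), n_f),
            "intensity": values.reshape(n_f, -1).ravel(),
            "is_internal_standard": is_std,
        })

    table = pd.concat([
        melt(sp["species"].to_numpy(), sp["lipid_class"].to_numpy(),
             sp["internal_standard_id"].to_numpy(), inten, False),
        melt(np.array([f"IS_{c}" for c in LIPID_CLASSES]),
             np.array(LIPID_CLASSES),
             np.array([f"IS_{c}" for c in LIPID_CLASSES]), is_inten, True),
    ], ignore_index=True)
    truth = pd.DataFrame({
        "species": sp["species"],
        "lipid_class": sp["lipid_class"],
        "mutant_fold_change": fold,
        "is_client_partner": is_partner,
    })
    log_stage("simulate_lipidome", len(table), len(table), seed=spec.seed)
    return table, truth


# ---------------------------------------------------------------------------
# Transcriptome and interactome
# ---------------------------------------------------------------------------

def _partner_transcripts(spec: SimulationSpec) -> dict[int, list[str]]:
    ids = [f"T{i:04d}" for i in range(spec.n_transcripts)]
    need = spec.n_planted_clients * spec.partners_per_client
    if need > spec.n_transcripts:
        raise ValidationError("not enough transcripts for client partners")
    return {i: ids[i * spec.partners_per_client:(i + 1) * spec.partners_per_client]
            for i in range(spec.n_planted_clients)}


def simulate_transcriptome(spec: SimulationSpec
                           ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Transcript feature matrix (features x samples) plus feature truth.

    The matrix emulates a pre-normalized expression table (positive,
    lognormal); a fraction of features carries a mutant fold change so the
    matrix has differential structure, and designated partner features share
    the planted clients' latent factor with negative sign.
    """
    rng = _rng(spec, "transcriptome")
    design = spec.design
    samples = design.sample_ids()
    z = latent_factor(spec).to_numpy()
    n_t = spec.n_transcripts
    ids = [f"T{i:04d}" for i in range(n_t)]
    partners = _partner_transcripts(spec)
    partner_idx = sorted({ids.index(t) for lst in partners.values() for t in lst})

    base = 1000.0 * np.exp(rng.normal(0.0, 1.0, n_t))
    n_aff = int(round(spec.frac_transcripts_affected * n_t))
    affected = rng.choice(n_t, size=n_aff, replace=False)

    mutant_mask = np.array([s.rsplit("_", 2)[0] != design.reference_genotype
                            for s in samples])
    level = np.tile(base[:, None], (1, len(samples)))
    level[np.ix_(affected, np.flatnonzero(mutant_mask))] *= spec.transcript_fold_change
    # partner transcripts: depleted in mutants and anti-correlated with z
    level[np.ix_(partner_idx, np.flatnonzero(mutant_mask))] *= 0.5
    level[partner_idx, :] = level[partner_idx, :] * np.exp(
        -spec.partner_loading * z[None, :])
    noise = np.exp(rng.normal(0.0, spec.transcript_sd, level.shape))
    matrix = pd.DataFrame(level * noise, index=ids, columns=samples)
    matrix.index.name = "feature_id"

    truth = pd.DataFrame({
        "feature_id": ids,
        "is_affected": np.isin(np.arange(n_t), affected),
        "is_client_partner": np.isin(np.arange(n_t), partner_idx),
    })
    log_stage("simulate_transcriptome", n_t, n_t, seed=spec.seed)
    return matrix, truth


def simulate_interactome(spec: SimulationSpec, truth: pd.DataFrame
                         ) -> pd.DataFrame:
    """Bait-pulldown enrichment table: interactors > 10, decoys <= 10."""
    if spec.n_planted_clients > spec.n_interactors:
        raise ValidationError("n_planted_clients cannot exceed n_interactors")
    rng = _rng(spec, "interactome")
    inter = truth.loc[truth["is_interactor"], "protein_id"].tolist()
    non = truth.loc[~truth["is_interactor"], "protein_id"].tolist()
    decoys = list(rng.choice(non, size=min(spec.n_decoy_interactome, len(non)),
                             replace=False))
    ratios_in = 10.0 * np.exp(rng.exponential(0.8, len(inter))) + 0.5
    ratios_out = rng.uniform(0.5, 10.0, len(decoys))
    out = pd.DataFrame({
        "protein_id": inter + decoys,
        "enrichment_ratio": np.concatenate([ratios_in, ratios_out]),
    })
    log_stage("simulate_interactome", len(out), len(out), seed=spec.seed)
    return out.reset_index(drop=True)


def client_partner_map(spec: SimulationSpec, truth: pd.DataFrame
                       ) -> pd.DataFrame:
    """Long table mapping each planted client to its partner features."""
    clients = truth.loc[truth["is_planted_client"], "protein_id"].tolist()
    lip = _partner_lipids(spec)
    tra = _partner_transcripts(spec)
    rows = []
    for i, pid in enumerate(clients):
        for s in lip[i]:
            rows.append((pid, "lipid", s))
        for t in tra[i]:
            rows.append((pid, "transcript", t))
    return pd.DataFrame(rows, columns=["protein_id", "layer", "feature_id"])


def simulate_all(spec: SimulationSpec) -> dict:
    """Every pipeline input plus ground truth, mutually consistent."""
    truth = protein_truth(spec)
    peptides, _ = simulate_turnover(spec)
    lipids, lipid_truth = simulate_lipidome(spec)
    transcripts, transcript_truth = simulate_transcriptome(spec)
    interactome = simulate_interactome(spec, truth)
    partners = client_partner_map(spec, truth)
    return {
        "peptides": peptides,
        "protein_truth": truth,
        "lipids": lipids,
        "lipid_truth": lipid_truth,
        "transcripts": transcripts,
        "transcript_truth": transcript_truth,
        "interactome": interactome,
        "client_partners": partners,
    }
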