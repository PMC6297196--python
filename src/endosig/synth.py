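"""Synthetic cohorts, quantification data, networks and gene sets.

Every downstream stage is testable without any download: this module
generates data with the statistical structure those stages assume —

* a subject table whose CSF (tTau, Abeta42) pair is bivariate log-normal with
  a configurable negative correlation, plus demographic/clinical covariates
  and endpoint labels (PET status, MCI conversion) coupled to the CSF
  pathology score;
* a protein concentration matrix, log-normal, in which a chosen subset of
  "signal" proteins carries a planted linear effect of the standardized
  pathology score on the log10 scale, together with small covariate and
  batch effects;
* peptide-level TMT 6-plex data (five study channels + a pooled reference
  channel per plex, the reference being the arithmetic mean of the five study
  channels), with multi-peptide, multi-isoform structure and per-plex isoform
  dropout;
* ELISA plates with duplicate wells and a standard series generated from a
  5-parameter logistic forward model;
* a scored interaction network with a planted high-confidence module on the
  signal proteins and extra unmeasured interactors;
* gene-set collections containing enriched (signal-bearing) and null sets.

All generators are deterministic given the config seed: each draws from an
independent, fixed substream of ``numpy.random.default_rng``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .endotype import pathology_score
from .quantify import FivePLCurve

TMT_STUDY_CHANNELS = ("TMT126", "TMT127", "TMT128", "TMT129", "TMT130")
TMT_REF_CHANNEL = "TMT131"
CENTERS = ("Perugia", "Barcelona", "Milan")

# Substream keys: one per generator, so adding draws to one generator never
# perturbs another.
_STREAMS = {"cohort": 1, "tmt": 2, "network": 3, "gene_sets": 4, "elisa": 5}


@dataclass(frozen=True)
class SimConfig:
    """Generator configuration.

    Defaults describe the emulated study: ~100 subjects stratified by CSF
    pathology, 200 proteins of which 10 carry a planted effect of 0.8 sd per
    unit pathology z-score on the log10 concentration scale, three peptides
    per protein, negative tau/Abeta42 correlation of -0.4.
    """

    n_subjects: int = 100
    n_proteins: int = 200
    n_signal_proteins: int = 10
    effect_size: float = 0.8
    csf_corr: float = -0.4
    covariate_effects: dict = field(default_factory=lambda: {
        "age": 0.05, "sex": 0.03, "apoe_e4": 0.05, "storage_years": 0.03})
    peptides_per_protein: int = 3
    isoform_prob: float = 0.3
    plex_missing_prob: float = 0.1
    batch_sd: float = 0.05
    noise_sd: float = 0.2
    ptau_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects <= 0 or self.n_proteins <= 0 or self.peptides_per_protein <= 0:
            raise ValueError("dimensions must be positive")
        if not 0 <= self.n_signal_proteins <= self.n_proteins:
            raise ValueError("n_signal_proteins must lie in [0, n_proteins]")
        if not -1 <= self.csf_corr <= 0:
            raise ValueError("csf_corr must lie in [-1, 0]")
        for name, p in (("isoform_prob", self.isoform_prob),
                        ("plex_missing_prob", self.plex_missing_prob)):
            if not 0 <= p <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.batch_sd < 0 or self.noise_sd <= 0:
            raise ValueError("batch_sd must be >= 0 and noise_sd > 0")

    def rng(self, stream: str) -> np.random.Generator:
        return np.random.default_rng([_STREAMS[stream], self.seed])


@dataclass
class GroundTruth:
    """Which proteins carry planted signal, and how much."""

    signal_protein_ids: set
    effects: dict


def _protein_ids(n: int) -> list[str]:
    return [f"P{i:04d}" for i in range(1, n + 1)]


def simulate_cohort(config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Subject table, protein concentration matrix, ground truth.

    CSF tTau and Abeta42 are bivariate log-normal with log-scale correlation
    ``csf_corr`` (both positive); pTau is ``ptau_fraction`` * tTau plus noise.
    Signal proteins shift by ``effect_size`` standard deviations of log10
    concentration per unit of the standardized pathology score; covariate and
    batch effects are added on the same scale. Deterministic given the seed.
    """
    rng = config.rng("cohort")
    n = config.n_subjects
    subject_ids = [f"S{i:04d}" for i in range(1, n + 1)]

    # CSF: log-normal pair with negative correlation (more tau, less Abeta42).
    cov = np.array([[0.45 ** 2, config.csf_corr * 0.45 * 0.35],
                    [config.csf_corr * 0.45 * 0.35, 0.35 ** 2]])
    log_csf = rng.multivariate_normal([np.log(400.0), np.log(650.0)], cov, size=n)
    ttau = np.exp(log_csf[:, 0])
    abeta42 = np.exp(log_csf[:, 1])
    ptau = config.ptau_fraction * ttau * np.exp(rng.normal(0, 0.1, n))

    x = pathology_score(ttau, abeta42)
    path_z = (np.log(x) - np.log(x).mean()) / np.log(x).std(ddof=0)

    age = rng.normal(67.0, 8.0, n)
    sex = rng.integers(0, 2, n)
    # Covariates that shift protein levels are drawn independently of the
    # pathology score; a pathology-linked covariate would confound the
    # *unadjusted* battery tests and break the null type-I calibration the
    # generator guarantees.
    apoe = (rng.random(n) < 0.4).astype(int)
    storage = rng.uniform(0.5, 8.0, n)
    bmi = rng.normal(26.5, 4.0, n)
    diabetes = (rng.random(n) < 0.08).astype(int)
    center = rng.choice(CENTERS, size=n, p=[0.5, 0.3, 0.2])
    n_batches = max(1, int(np.ceil(n / 20)))
    batch = rng.permutation(np.repeat([f"B{b + 1}" for b in range(n_batches)],
                                      20))[:n]
    pet = (path_z + rng.normal(0, 0.6, n) > 0).astype(int)
    diag_p = np.clip(0.15 + 0.30 * path_z, 0.02, 0.95)
    u = rng.random(n)
    diagnosis = np.where(u < diag_p, "AD", np.where(u < diag_p + 0.35, "MCI", "SCD"))
    converter = ((diagnosis == "MCI")
                 & (path_z + rng.normal(0, 0.8, n) > 0.3)).astype(int)

    subjects = pd.DataFrame({
        "diagnosis": diagnosis, "age": age, "sex": sex, "apoe_e4": apoe,
        "ttau": ttau, "abeta42": abeta42, "ptau": ptau,
        "pet_status": pet, "mci_converter": converter,
        "cohort": center, "center": center, "batch": batch,
        "storage_years": storage, "bmi": bmi, "diabetes": diabetes,
    }, index=pd.Index(subject_ids, name="subject"))

    proteins = _protein_ids(config.n_proteins)
    signal_idx = rng.choice(config.n_proteins, size=config.n_signal_proteins,
                            replace=False)
    effects = np.zeros(config.n_proteins)
    effects[signal_idx] = config.effect_size * rng.choice([-1.0, 1.0],
                                                          size=config.n_signal_proteins)
    baseline = rng.normal(1.5, 0.5, config.n_proteins)

    cov_z = {}
    for name in config.covariate_effects:
        col = subjects[name].to_numpy(dtype=float)
        sd = col.std(ddof=0)
        cov_z[name] = (col - col.mean()) / (sd if sd > 0 else 1.0)
    cov_shift = sum(beta * cov_z[name]
                    for name, beta in config.covariate_effects.items())
    batch_codes = pd.factorize(subjects["batch"])[0]
    batch_offsets = rng.normal(0, config.batch_sd,
                               size=(config.n_proteins, batch_codes.max() + 1))

    # log10 concentration per protein x subject; planted effects scale with
    # the per-protein noise sd so effect_size is a standardized shift.
    log10_conc = (baseline[:, None]
                  + effects[:, None] * config.noise_sd * path_z[None, :]
                  + np.broadcast_to(cov_shift, (config.n_proteins, n))
                  + batch_offsets[:, batch_codes]
                  + rng.normal(0, config.noise_sd, (config.n_proteins, n)))
    matrix = pd.DataFrame(np.power(10.0, log10_conc),
                          index=pd.Index(proteins, name="protein"),
                          columns=subjects.index)
    truth = GroundTruth(
        signal_protein_ids={proteins[i] for i in signal_idx},
        effects={proteins[i]: float(effects[i]) for i in range(config.n_proteins)})
    return subjects, matrix, truth


def simulate_tmt(matrix: pd.DataFrame, config: SimConfig):
    """Peptide-level TMT 6-plex data from a protein concentration matrix.

    Subjects are tiled into plexes of five study channels; the reference
    channel is the arithmetic mean of the five (a pooled reference). Each
    protein yields ``peptides_per_protein`` peptides (with peptide-specific
    ionization efficiencies); with probability ``isoform_prob`` a protein
    emits a second MW-isoform block with its own peptides at half abundance.
    Whole isoform blocks drop out of a plex with ``plex_missing_prob``.
    Returns a :class:`~endosig.quantify.PeptideQuantSet`.
    """
    from .quantify import PeptideQuantSet  # local import avoids cycle at module load

    if matrix.shape[1] < 1:
        raise ValueError("need at least one subject")
    rng = config.rng("tmt")
    samples = list(matrix.columns)
    n_plex = int(np.ceil(len(samples) / len(TMT_STUDY_CHANNELS)))
    records = []
    for prot in matrix.index:
        conc = matrix.loc[prot].to_numpy(dtype=float)
        n_iso = 2 if rng.random() < config.isoform_prob else 1
        for iso in range(1, n_iso + 1):
            iso_scale = 1.0 if iso == 1 else 0.5
            eff = np.exp(rng.normal(2.0, 0.8, config.peptides_per_protein))
            dropout = rng.random(n_plex) < config.plex_missing_prob
            for plex in range(n_plex):
                if dropout[plex]:
                    continue
                lo = plex * len(TMT_STUDY_CHANNELS)
                idx = list(range(lo, min(lo + len(TMT_STUDY_CHANNELS), len(samples))))
                for pep in range(1, config.peptides_per_protein + 1):
                    noise = np.exp(rng.normal(0, config.noise_sd * np.log(2),
                                              len(idx)))
                    intens = conc[idx] * iso_scale * eff[pep - 1] * noise
                    for j, i_samp in enumerate(idx):
                        records.append((f"plex{plex + 1}", TMT_STUDY_CHANNELS[j],
                                        prot, iso, f"{prot}_iso{iso}_pep{pep}",
                                        intens[j], samples[i_samp]))
                    records.append((f"plex{plex + 1}", TMT_REF_CHANNEL, prot, iso,
                                    f"{prot}_iso{iso}_pep{pep}",
                                    float(np.mean(intens)), "pooled_reference"))
    rec = pd.DataFrame(records, columns=["plex", "channel", "protein", "isoform",
                                         "peptide", "intensity", "sample"])
    return PeptideQuantSet(records=rec, ref_channel=TMT_REF_CHANNEL)


def simulate_network(config: SimConfig, truth: GroundTruth | None = None,
                     density: float = 0.02, n_extra: int | None = None) -> nx.Graph:
    """Scored undirected interaction network.

    Random background edges at the given density with confidences in
    [0.2, 1); a planted clique over the signal proteins at confidence >= 0.7;
    extra nodes absent from the measured panel (ids ``X...``), each attached
    to a few measured proteins, so network expansion is exercised.
    """
    if config.n_proteins < 2:
        raise ValueError("need at least 2 proteins for a network")
    if not 0 <= density <= 1:
        raise ValueError("density must lie in [0, 1]")
    rng = config.rng("network")
    proteins = _protein_ids(config.n_proteins)
    n_extra = config.n_proteins // 4 if n_extra is None else n_extra
    extras = [f"X{i:04d}" for i in range(1, n_extra + 1)]
    g = nx.Graph()
    g.add_nodes_from(proteins + extras)
    nodes = proteins + extras
    if density > 0:
        n_nodes = len(nodes)
        n_possible = n_nodes * (n_nodes - 1) // 2
        n_edges = rng.binomial(n_possible, density)
        iu = np.triu_indices(n_nodes, k=1)
        pick = rng.choice(n_possible, size=n_edges, replace=False)
        for e in pick:
            u, v = nodes[iu[0][e]], nodes[iu[1][e]]
            g.add_edge(u, v, confidence=float(rng.uniform(0.2, 1.0)))
        for xnode in extras:
            for prot in rng.choice(proteins, size=min(3, len(proteins)),
                                   replace=False):
                if not g.has_edge(xnode, prot):
                    g.add_edge(xnode, prot, confidence=float(rng.uniform(0.45, 1.0)))
    if truth is not None and truth.signal_protein_ids:
        sig = sorted(truth.signal_protein_ids)
        for i, u in enumerate(sig):
            for v in sig[i + 1:]:
                g.add_edge(u, v, confidence=float(rng.uniform(0.7, 1.0)))
    return g


def simulate_gene_sets(config: SimConfig, truth: GroundTruth, n_null_sets: int = 9,
                       set_size: int = 20, signal_fraction: float = 0.8,
                       universe: list | None = None) -> dict:
    """Gene-set collection with one enriched set and ``n_null_sets`` null sets.

    The enriched set contains at least ``signal_fraction`` of the signal
    proteins, padded with random genes up to ``set_size``; null sets are
    uniform draws from the universe. With no signal proteins all sets are
    null. Raises if ``set_size`` exceeds the universe.
    """
    rng = config.rng("gene_sets")
    universe = list(universe) if universe is not None else _protein_ids(config.n_proteins)
    if set_size > len(universe):
        raise ValueError(f"set size {set_size} exceeds universe of {len(universe)}")
    sets: dict = {}
    signal = sorted(truth.signal_protein_ids)
    if signal:
        n_take = max(1, int(np.ceil(signal_fraction * len(signal))))
        members = list(rng.choice(signal, size=min(n_take, len(signal)),
                                  replace=False))
        pool = [u for u in universe if u not in members]
        pad = max(0, min(set_size, len(universe)) - len(members))
        members += list(rng.choice(pool, size=pad, replace=False))
        sets["enriched_1"] = set(members)
    for i in range(1, n_null_sets + 1):
        sets[f"null_{i}"] = set(rng.choice(universe, size=set_size, replace=False))
    return sets


def simulate_elisa_plate(true_concentrations: pd.Series, curve: FivePLCurve,
                         noise_sd: float = 0.0, seed: int | None = 0,
                         n_standards: int = 8) -> pd.DataFrame:
    """One ELISA plate: a duplicate standard series plus duplicate sample wells.

    Absorbances come from the 5PL forward model of ``curve`` plus Gaussian
    noise of sd ``noise_sd``. Standards span the curve geometrically around
    the midpoint concentration ``c``. Returns a long table with columns
    (id, kind, concentration, replicate, absorbance); sample concentrations
    are recorded for ground-truthing but would be unknown in a real assay.
    """
    conc = true_concentrations.astype(float)
    if (conc <= 0).any():
        raise ValueError("sample concentrations must be > 0")
    rng = np.random.default_rng(seed)
    standards = curve.c * np.power(4.0, np.linspace(-3.0, 4.0, n_standards))
    rows = []
    for i, sconc in enumerate(standards, start=1):
        for rep in (1, 2):
            y = curve.forward(sconc) + rng.normal(0, noise_sd)
            rows.append((f"STD{i}", "standard", float(sconc), rep, float(y)))
    for sid, sconc in conc.items():
        for rep in (1, 2):
            y = curve.forward(sconc) + rng.normal(0, noise_sd)
            rows.append((sid, "sample", float(sconc), rep, float(y)))
    return pd.DataFrame(rows, columns=["id", "kind", "concentration",
                                       "replicate", "absorbance"])
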