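"""Synthetic two-cohort gut-metagenome data with planted ground truth.

The generator emulates the statistical structure of a two-cohort case/control
metagenome study of chronic kidney disease:

* heavy-tailed species relative abundances (log-normal per species with a
  power-law-like mean spectrum, zero-inflated, renormalized to compositions);
* a planted set of differential species shifted in cases by a signed log2
  fold change, scaled along a CKD severity gradient
  (HC < CKD3/4 < CKD5N < ESRD);
* cohort-level random log-abundance offsets applied identically to cases and
  controls of a cohort, reproducing "cohort origin" as an independent
  variance component;
* serum uremic-toxin concentrations (IS, PCS, PAG, TMAO) linearly driven on
  the log scale by a planted contributor subset plus Gaussian noise;
* genome bins with planted identity clusters for dereplication tests; and
* species x KO presence matrices in which planted functions co-occur with the
  planted enrichment direction.

Every generated quantity is reproducible from ``SimulationConfig.seed``; the
planted truth is returned alongside the data so downstream recovery can be
scored.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .catalog import MAGRecord, ValidationError

GROUP_ORDER = ("HC", "CKD3_4", "CKD5N", "ESRD")
TOXINS = ("IS", "PCS", "PAG", "TMAO")

_PHYLA = (
    "Firmicutes",
    "Bacteroidetes",
    "Proteobacteria",
    "Actinobacteria",
    "Verrucomicrobia",
    "Fusobacteria",
)


class ConfigurationError(ValueError):
    """Raised when a simulation configuration violates its invariants."""


def _default_arms():
    return {
        ("SH", "HC"): 100,
        ("SH", "ESRD"): 100,
        ("BJ", "HC"): 100,
        ("BJ", "ESRD"): 100,
    }


@dataclass
class SimulationConfig:
    """Study-design parameters of the synthetic cohorts.

    ``severity_gradient`` gives the effect multiplier per group in the order
    HC, CKD3/4, CKD5N, ESRD; HC is the control arm (multiplier 0) and the
    multipliers must be nondecreasing in magnitude.
    """

    n_species: int = 300
    n_per_arm: dict = field(default_factory=_default_arms)
    frac_differential: float = 50 / 300
    effect_log2fc: float = 1.5
    cohort_shift_sd: float = 0.5
    severity_gradient: tuple = (0.0, 0.5, 0.8, 1.0)
    n_toxin_contributors: int = 10
    toxin_noise_sd: float = 1.0
    seed: int = 0
    # shape parameters of the base composition
    log_sd: float = 1.0
    mean_spectrum_slope: float = 1.5
    prevalence_range: tuple = (0.7, 1.0)
    # KO-presence layer
    n_functions: int = 200
    n_planted_functions: int = 30
    planted_presence: float = 0.9
    background_presence: float = 0.35

    def __post_init__(self):
        if self.n_species < 1:
            raise ConfigurationError("n_species must be >= 1")
        if not self.n_per_arm or any(n < 1 for n in self.n_per_arm.values()):
            raise ConfigurationError("every arm needs >= 1 sample")
        # YAML configs spell arms as "COHORT:GROUP" (or "COHORT,GROUP")
        norm = {}
        for key, n in self.n_per_arm.items():
            if isinstance(key, str):
                key = tuple(key.replace(",", ":").split(":"))
            key = tuple(key)
            if len(key) != 2:
                raise ConfigurationError(f"bad arm key {key!r}")
            norm[key] = int(n)
        self.n_per_arm = norm
        if not 0 <= self.frac_differential <= 1:
            raise ConfigurationError("frac_differential must be in [0, 1]")
        if self.effect_log2fc < 0:
            raise ConfigurationError("effect_log2fc must be >= 0")
        if self.cohort_shift_sd < 0 or self.toxin_noise_sd < 0:
            raise ConfigurationError("standard deviations must be >= 0")
        if self.n_toxin_contributors < 1:
            raise ConfigurationError("n_toxin_contributors must be >= 1")
        grad = tuple(float(g) for g in self.severity_gradient)
        if len(grad) != 4 or any(
            abs(a) > abs(b) for a, b in zip(grad, grad[1:])
        ):
            raise ConfigurationError(
                "severity_gradient needs 4 multipliers, nondecreasing in magnitude"
            )
        self.severity_gradient = grad
        for (cohort, group) in self.n_per_arm:
            if group not in GROUP_ORDER:
                raise ConfigurationError(f"unknown group {group!r}")

    @property
    def severity_multiplier(self) -> dict:
        return dict(zip(GROUP_ORDER, self.severity_gradient))


@dataclass
class GroundTruth:
    """Planted structure of a simulated data set.

    ``differential_species`` maps species id to +1 (case-enriched) or -1
    (control-enriched).  ``toxin_contributors`` maps each toxin to its
    contributor species and log-scale weights.  ``signal_fractions`` records
    the realized variance fraction of each toxin explained by the planted
    linear part.  ``planted_module_assignments`` maps function id to the
    enrichment direction of the species set it co-occurs with.
    """

    differential_species: dict = field(default_factory=dict)
    toxin_contributors: dict = field(default_factory=dict)
    planted_module_assignments: dict = field(default_factory=dict)
    signal_fractions: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        payload = {
            "differential_species": self.differential_species,
            "toxin_contributors": {
                t: {"species": list(s), "weights": list(map(float, w))}
                for t, (s, w) in self.toxin_contributors.items()
            },
            "planted_module_assignments": self.planted_module_assignments,
            "signal_fractions": self.signal_fractions,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    # independent, named substreams derived from the master seed
    return np.random.default_rng(np.random.SeedSequence((config.seed, stream)))


def generate_species_catalog(config: SimulationConfig) -> pd.DataFrame:
    """Species catalog with a consistent phylum > family > genus hierarchy.

    Besides taxonomy and assembly-quality columns, each species carries its
    base log-abundance (power-law-like mean spectrum, rank decoupled from the
    id order) and its prevalence (fraction of samples carrying it), which the
    abundance generator consumes.
    """
    rng = _rng(config, 0)
    n = config.n_species
    rows = []
    for i in range(n):
        phylum = _PHYLA[i % len(_PHYLA)]
        fam_idx = (i // len(_PHYLA)) % 3
        family = f"{phylum[:4]}aceae{fam_idx + 1}"
        gen_idx = (i // (len(_PHYLA) * 3)) % 4
        genus = f"{family}_g{gen_idx + 1}"
        rows.append(
            {
                "id": f"s{i + 1:04d}",
                "phylum": phylum,
                "family": family,
                "genus": genus,
                "completeness": float(rng.uniform(70, 100)),
                "contamination": float(rng.uniform(0, 5)),
                "gc": float(rng.uniform(0.28, 0.68)),
            }
        )
    df = pd.DataFrame(rows).set_index("id", drop=False)
    log_mean = -config.mean_spectrum_slope * np.log(np.arange(1, n + 1))
    df["log_mean"] = log_mean[rng.permutation(n)]
    lo, hi = config.prevalence_range
    df["prevalence"] = rng.uniform(lo, hi, size=n)
    return df


def make_ground_truth(catalog: pd.DataFrame, config: SimulationConfig) -> GroundTruth:
    """Draw the planted differential species, toxin contributors, functions."""
    rng = _rng(config, 1)
    species = list(catalog["id"])
    n_diff = int(round(config.frac_differential * len(species)))
    chosen = rng.choice(species, size=n_diff, replace=False)
    signs = rng.choice([1, -1], size=n_diff)
    # guarantee both directions whenever >= 2 species are planted
    if n_diff >= 2 and len(set(signs)) == 1:
        signs[0] = -signs[0]
    truth = GroundTruth(
        differential_species={s: int(g) for s, g in zip(chosen, signs)}
    )
    # toxin producers are prevalent commensals: contributors come from the
    # high-prevalence stratum so their log-abundances are well defined in
    # nearly every sample
    if "prevalence" in catalog.columns:
        eligible = list(catalog.loc[catalog["prevalence"] >= 0.9, "id"])
        if len(eligible) < config.n_toxin_contributors:
            eligible = list(
                catalog.sort_values("prevalence", ascending=False)["id"][
                    : max(config.n_toxin_contributors, len(species) // 4)
                ]
            )
    else:
        eligible = species
    for toxin in TOXINS:
        contributors = rng.choice(
            eligible, size=min(config.n_toxin_contributors, len(eligible)),
            replace=False,
        )
        # every planted contributor carries recoverable weight: magnitudes
        # bounded away from zero, random sign
        weights = rng.uniform(0.5, 1.5, size=len(contributors)) * rng.choice(
            [1.0, -1.0], size=len(contributors)
        )
        truth.toxin_contributors[toxin] = (list(contributors), list(weights))
    return truth


def generate_cohort_abundances(
    catalog: pd.DataFrame, config: SimulationConfig, truth: GroundTruth
):
    """Relative-abundance table and sample metadata for all cohorts/arms.

    Log-abundance model per species i, sample s in cohort c, group g:
    ``mu_i + o_ic + sign_i * effect * ln2 * m_g + eps`` with eps ~ N(0, log_sd),
    followed by per-species zero-inflation (prevalence shared by all arms) and
    row renormalization to a composition.
    """
    missing = set(truth.differential_species) - set(catalog["id"])
    if missing:
        raise ValidationError(f"planted species not in catalog: {sorted(missing)}")
    rng = _rng(config, 2)
    species = list(catalog["id"])
    n_sp = len(species)
    if "log_mean" in catalog.columns:
        mu = catalog["log_mean"].values.astype(float)
        prevalence = catalog["prevalence"].values.astype(float)
    else:  # minimal catalogs (id/taxonomy only): draw the spectrum here
        mu = -config.mean_spectrum_slope * np.log(np.arange(1, n_sp + 1))
        mu = mu[rng.permutation(n_sp)]
        lo, hi = config.prevalence_range
        prevalence = rng.uniform(lo, hi, size=n_sp)
    sign = np.zeros(n_sp)
    for sp, d in truth.differential_species.items():
        sign[species.index(sp)] = d
    mult = config.severity_multiplier

    cohorts = sorted({c for c, _ in config.n_per_arm})
    rows, meta = [], []
    for cohort in cohorts:
        offset = rng.normal(0.0, config.cohort_shift_sd, size=n_sp)
        for group in GROUP_ORDER:
            n_arm = config.n_per_arm.get((cohort, group), 0)
            if n_arm == 0:
                continue
            shift = sign * config.effect_log2fc * np.log(2) * mult[group]
            for k in range(n_arm):
                eps = rng.normal(0.0, config.log_sd, size=n_sp)
                x = np.exp(mu + offset + shift + eps)
                present = rng.random(n_sp) < prevalence
                if not present.any():
                    present[rng.integers(n_sp)] = True
                x = np.where(present, x, 0.0)
                rows.append(x / x.sum())
                meta.append(
                    {
                        "sample_id": f"{cohort}_{group}_{k + 1:03d}",
                        "cohort": cohort,
                        "group": group,
                        "is_case": group != "HC",
                        "sex": ("F", "M")[int(rng.integers(2))],
                        "age": float(np.clip(rng.normal(54, 12), 20, 90)),
                        "bmi": float(np.clip(rng.normal(24, 3), 15, 40)),
                    }
                )
    metadata = pd.DataFrame(meta).set_index("sample_id", drop=False)
    table = pd.DataFrame(rows, index=metadata.index, columns=species)
    return table, metadata


def generate_toxin_concentrations(
    table: pd.DataFrame, truth: GroundTruth, config: SimulationConfig
) -> pd.DataFrame:
    """Serum toxin concentrations driven by planted contributor species.

    The linear predictor is a weighted sum of contributor log-abundances,
    standardized to unit variance; Gaussian noise with sd
    ``toxin_noise_sd`` is added on the log scale and the result exponentiated,
    so concentrations are positive and log-linear in the contributors.  The
    realized signal fraction var(signal)/var(total) is recorded in ``truth``.
    """
    rng = _rng(config, 3)
    out = {}
    for toxin, (species_ids, weights) in truth.toxin_contributors.items():
        missing = set(species_ids) - set(table.columns)
        if missing:
            raise ValidationError(
                f"toxin {toxin}: contributors absent from table: {sorted(missing)}"
            )
        sub = table[list(species_ids)].values
        # per-species pseudocount: half the species' own smallest nonzero
        # abundance, so an absent contributor is a mild shortfall rather than
        # an extreme leverage point on the log scale
        pseudo = np.array([
            0.5 * col[col > 0].min() if (col > 0).any() else 1e-12
            for col in sub.T
        ])
        logx = np.log(sub + pseudo)
        signal = logx @ np.asarray(weights, dtype=float)
        sd = signal.std()
        if sd > 0:
            signal = (signal - signal.mean()) / sd
        noise = rng.normal(0.0, config.toxin_noise_sd, size=len(signal))
        total = signal + noise
        denom = signal.var() + config.toxin_noise_sd**2
        truth.signal_fractions[toxin] = float(
            signal.var() / denom if denom > 0 else 0.0
        )
        out[toxin] = np.exp(total)
    return pd.DataFrame(out, index=table.index)


def noise_sd_for_signal_fraction(f: float) -> float:
    """Toxin noise sd that plants signal fraction ``f`` on a unit-variance signal."""
    if not 0 < f <= 1:
        raise ConfigurationError("signal fraction must be in (0, 1]")
    return float(np.sqrt(1.0 / f - 1.0))


def generate_bins(
    n_bins: int,
    config: SimulationConfig,
    cluster_size: int = 3,
    within_identity: float = 0.98,
    between_identity: float = 0.85,
):
    """Genome bins with planted identity clusters for dereplication tests.

    Returns (records, identity matrix, planted labels).  Bins are assigned to
    clusters of ``cluster_size`` consecutive bins; pairwise identity is
    ``within_identity`` inside a cluster and ``between_identity`` across
    clusters.  Depth/GC/species labels are cluster-coherent so the same
    fixtures also exercise the within-sample merge heuristic.
    """
    if n_bins < 1:
        raise ConfigurationError("n_bins must be >= 1")
    rng = _rng(config, 4)
    labels = np.arange(n_bins) // cluster_size
    ids = [f"bin{i + 1:03d}" for i in range(n_bins)]
    records = []
    for i, bid in enumerate(ids):
        cl = labels[i]
        records.append(
            MAGRecord(
                id=bid,
                sample_id="S1",
                completeness=float(rng.uniform(75, 100)),
                contamination=float(rng.uniform(0, 4)),
                depth=float((cl + 1) * 10.0 * rng.uniform(0.97, 1.03)),
                gc=float(np.clip(0.35 + 0.05 * cl + rng.normal(0, 0.004), 0, 1)),
                taxonomy=("Bacteria", "", "", "", "", "", f"sp_cluster_{cl}"),
            )
        )
    m = np.full((n_bins, n_bins), between_identity)
    same = labels[:, None] == labels[None, :]
    m[same] = within_identity
    np.fill_diagonal(m, 1.0)
    identity = pd.DataFrame(m, index=ids, columns=ids)
    return records, identity, labels


def generate_ko_presence(
    catalog: pd.DataFrame, truth: GroundTruth, config: SimulationConfig
) -> pd.DataFrame:
    """Species x KO boolean matrix with planted direction-coherent functions.

    The first ``n_planted_functions`` KOs are planted: a KO assigned direction
    +1 is present in case-enriched species with probability
    ``planted_presence`` and elsewhere with ``1 - planted_presence`` (and
    symmetrically for -1).  Remaining KOs are background with uniform
    presence probability.  Assignments are recorded in
    ``truth.planted_module_assignments``.
    """
    rng = _rng(config, 5)
    species = list(catalog["id"])
    n_fn = config.n_functions
    n_planted = min(config.n_planted_functions, n_fn)
    kos = [f"K{j + 1:05d}" for j in range(n_fn)]
    direction = {s: d for s, d in truth.differential_species.items()}
    mat = np.zeros((len(species), n_fn), dtype=bool)
    p_hi, p_lo = config.planted_presence, 1.0 - config.planted_presence
    for j in range(n_fn):
        if j < n_planted:
            d = 1 if j % 2 == 0 else -1
            truth.planted_module_assignments[kos[j]] = d
            p = np.array(
                [p_hi if direction.get(s, 0) == d else p_lo for s in species]
            )
        else:
            p = np.full(len(species), config.background_presence)
        mat[:, j] = rng.random(len(species)) < p
    return pd.DataFrame(mat, index=pd.Index(species, name="species"), columns=kos)


def simulate_all(config: SimulationConfig):
    """One-call generation of every synthetic artifact plus its ground truth."""
    catalog = generate_species_catalog(config)
    truth = make_ground_truth(catalog, config)
    table, metadata = generate_cohort_abundances(catalog, config, truth)
    toxins = generate_toxin_concentrations(table, truth, config)
    ko_presence = generate_ko_presence(catalog, truth, config)
    bins, identity, _ = generate_bins(
        min(30, 3 * max(1, config.n_species // 10)), config
    )
    return {
        "catalog": catalog,
        "truth": truth,
        "abundance": table,
        "metadata": metadata,
        "toxins": toxins,
        "ko_presence": ko_presence,
        "bins": bins,
        "identity": identity,
    }
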