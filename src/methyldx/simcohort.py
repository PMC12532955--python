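"""Synthetic whole-blood DNA-methylation cohorts.

Generates beta-value matrices (probes x samples), sample sheets and
ground-truth probe annotations with the statistical structure a
multi-disease methylation case-control study assumes: RA-specific and
shared-inflammation CpG effects, age and sex confounding, two array
versions with partially overlapping probe sets, and serology correlated
with case subtype.

The generative model is additive on the logit scale: for sample i and
probe j,

    beta_ij = logistic(mu_j + sum of planted deltas applicable to i + e_ij),
    e_ij ~ Normal(0, noise_sd),

where mu_j is drawn from a three-component mixture (hypo-, hemi-,
hyper-methylated probe classes) mimicking the bimodal beta distribution
of methylation arrays.  The logit-normal noise keeps beta in (0,1) and
makes M-value analysis exactly linear-Gaussian.
"""

from __future__ import annotations

import dataclasses
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit

__all__ = [
    "GROUPS",
    "RA_GROUPS",
    "INFLAMMATORY_GROUPS",
    "SimConfig",
    "ConfigError",
    "ParseError",
    "simulate_cohort",
    "split_by_array",
    "write_cohort",
    "read_cohort",
]

GROUPS = (
    "healthy",
    "ra_seropos",
    "ra_seroneg",
    "other_arthritis",
    "ibd",
    "ms",
    "sepsis",
)

#: groups whose members are RA cases
RA_GROUPS = frozenset({"ra_seropos", "ra_seroneg"})

#: groups carrying the full shared-inflammation effect; other_arthritis
#: receives half the effect so RA-vs-arthritis discrimination is harder
#: than RA-vs-healthy
INFLAMMATORY_GROUPS = frozenset({"ra_seropos", "ra_seroneg", "ibd", "ms", "sepsis"})

# uniform age ranges (years) per group; sepsis samples are newborns
_AGE_RANGES = {
    "healthy": (37.0, 62.0),
    "ra_seropos": (44.0, 62.0),
    "ra_seroneg": (46.0, 66.0),
    "other_arthritis": (26.0, 57.0),
    "ibd": (28.0, 52.0),
    "ms": (34.0, 47.0),
    "sepsis": (0.0, 0.0),
}

_FEMALE_FRAC = {
    "healthy": 0.64,
    "ra_seropos": 0.71,
    "ra_seroneg": 0.75,
    "other_arthritis": 0.45,
    "ibd": 0.46,
    "ms": 1.0,
    "sepsis": 0.24,
}

#: age effects are centred at this age so baselines stay near mu
AGE_CENTER = 45.0

EFFECT_CLASSES = ("ra_specific", "inflammation", "age", "sex", "null")


class ConfigError(ValueError):
    """Invalid simulation configuration."""


class ParseError(ValueError):
    """Malformed cohort file."""


def _default_group_sizes() -> dict[str, int]:
    # multi-disease discovery cohort sizes
    return {"healthy": 521, "ra_seropos": 354, "ibd": 204, "ms": 52, "sepsis": 17}


def _default_baseline_mixture() -> dict[str, tuple[float, ...]]:
    return {"weights": (0.4, 0.2, 0.4), "means": (-3.0, 0.0, 3.0)}


def _default_serology_rates() -> dict[str, float]:
    # P(ACPA+), P(RF+) among seropositive RA
    return {"acpa": 0.87, "rf": 0.93}


def _default_array_masks() -> dict[str, float]:
    # fraction of the probe set covered by each array version
    return {"EPIC": 1.0, "A450K": 0.8}


def _default_array_assignment() -> dict[str, str]:
    # sepsis samples come from an EPIC study, the rest from 450K studies
    return {g: ("EPIC" if g == "sepsis" else "A450K") for g in GROUPS}


@dataclass
class SimConfig:
    """Parameters of the cohort generator.

    All effect sizes are on the logit(beta) scale.  ``noise_sd`` is the
    within-group standard deviation of the logit-normal noise.
    """

    group_sizes: dict[str, int] = field(default_factory=_default_group_sizes)
    n_probes: int = 20_000
    n_ra_specific: int = 150
    n_inflammation: int = 150
    delta_ra: float = 1.0
    delta_inflam: float = 1.0
    age_slope: float = 0.02
    n_age_probes: int = 300
    sex_delta: float = 0.5
    n_sex_probes: int = 300
    noise_sd: float = 0.5
    baseline_mixture: dict = field(default_factory=_default_baseline_mixture)
    serology_rates: dict = field(default_factory=_default_serology_rates)
    array_masks: dict = field(default_factory=_default_array_masks)
    array_assignment: dict = field(default_factory=_default_array_assignment)
    id_prefix: str = "S"
    seed: int = 0

    def validate(self) -> None:
        for g in self.group_sizes:
            if g not in GROUPS:
                raise ConfigError(f"unknown group in group_sizes: {g!r}")
        for g, n in self.group_sizes.items():
            if n < 0:
                raise ConfigError(f"negative count for group {g!r}")
        counts = (
            self.n_ra_specific,
            self.n_inflammation,
            self.n_age_probes,
            self.n_sex_probes,
        )
        if any(c < 0 for c in counts):
            raise ConfigError("planted probe counts must be >= 0")
        if sum(counts) > self.n_probes:
            raise ConfigError(
                f"planted probe counts sum to {sum(counts)} > n_probes={self.n_probes}"
            )
        if not self.noise_sd > 0:
            raise ConfigError("noise_sd must be > 0")
        for k, v in self.serology_rates.items():
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"serology rate {k}={v} outside [0,1]")
        w = np.asarray(self.baseline_mixture["weights"], float)
        if np.any(w < 0) or not np.isclose(w.sum(), 1.0):
            raise ConfigError("baseline mixture weights must be >= 0 and sum to 1")
        for g, ver in self.array_assignment.items():
            if ver not in self.array_masks:
                raise ConfigError(f"array version {ver!r} for group {g!r} has no mask")

    def replace(self, **kw) -> "SimConfig":
        return dataclasses.replace(self, **kw)


def _probe_ids(n: int) -> list[str]:
    return [f"cg{i:08d}" for i in range(1, n + 1)]


def array_mask_probes(config: SimConfig, version: str) -> list[str]:
    """Probe ids covered by an array version (seeded, independent of samples)."""
    frac = config.array_masks[version]
    probes = np.array(_probe_ids(config.n_probes))
    if frac >= 1.0:
        return list(probes)
    rng = np.random.default_rng([config.seed, zlib.crc32(version.encode())])
    k = int(round(frac * config.n_probes))
    keep = np.sort(rng.choice(config.n_probes, size=k, replace=False))
    return list(probes[keep])


def simulate_cohort(
    config: SimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Draw one cohort.

    Returns
    -------
    beta : DataFrame, probes x samples, values in (0, 1)
    sheet : DataFrame with one row per sample (sample_id, group, age, sex,
        acpa, rf, array_version, split_role)
    truth : DataFrame with one row per probe (probe_id, effect_class,
        planted_delta)
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    probes = _probe_ids(config.n_probes)
    mix = config.baseline_mixture
    comp = rng.choice(len(mix["weights"]), size=config.n_probes, p=mix["weights"])
    mu = np.asarray(mix["means"], float)[comp]

    # disjoint planted probe sets
    perm = rng.permutation(config.n_probes)
    cuts = np.cumsum(
        [config.n_ra_specific, config.n_inflammation, config.n_age_probes, config.n_sex_probes]
    )
    idx_ra, idx_inf, idx_age, idx_sex = np.split(perm[: cuts[-1]], cuts[:-1])

    effect_class = np.full(config.n_probes, "null", dtype=object)
    planted = np.zeros(config.n_probes)
    effect_class[idx_ra] = "ra_specific"
    planted[idx_ra] = config.delta_ra
    effect_class[idx_inf] = "inflammation"
    planted[idx_inf] = config.delta_inflam
    effect_class[idx_age] = "age"
    planted[idx_age] = config.age_slope
    effect_class[idx_sex] = "sex"
    planted[idx_sex] = config.sex_delta
    truth = pd.DataFrame(
        {"probe_id": probes, "effect_class": effect_class, "planted_delta": planted}
    )

    rows = []
    k = 0
    for group in GROUPS:
        n = config.group_sizes.get(group, 0)
        lo, hi = _AGE_RANGES[group]
        for _ in range(n):
            k += 1
            age = float(lo) if hi == lo else float(rng.uniform(lo, hi))
            sex = "F" if rng.random() < _FEMALE_FRAC[group] else "M"
            acpa, rf = _draw_serology(group, config.serology_rates, rng)
            rows.append(
                {
                    "sample_id": f"{config.id_prefix}{k:05d}",
                    "group": group,
                    "age": round(age, 1),
                    "sex": sex,
                    "acpa": acpa,
                    "rf": rf,
                    "array_version": config.array_assignment.get(group, "EPIC"),
                    "split_role": "unassigned",
                }
            )
    sheet = pd.DataFrame(
        rows,
        columns=[
            "sample_id",
            "group",
            "age",
            "sex",
            "acpa",
            "rf",
            "array_version",
            "split_role",
        ],
    )
    n_samples = len(sheet)
    if n_samples == 0:
        raise ConfigError("group_sizes produce an empty cohort")

    is_ra = sheet["group"].isin(RA_GROUPS).to_numpy()
    is_inf = sheet["group"].isin(INFLAMMATORY_GROUPS).to_numpy()
    is_arth = (sheet["group"] == "other_arthritis").to_numpy()
    is_f = (sheet["sex"] == "F").to_numpy()
    age_c = sheet["age"].to_numpy() - AGE_CENTER

    lp = np.tile(mu[:, None], (1, n_samples))
    lp[idx_ra[:, None], np.where(is_ra)[0][None, :]] += config.delta_ra
    lp[idx_inf[:, None], np.where(is_inf)[0][None, :]] += config.delta_inflam
    lp[idx_inf[:, None], np.where(is_arth)[0][None, :]] += config.delta_inflam / 2.0
    lp[idx_age, :] += config.age_slope * age_c[None, :]
    lp[idx_sex[:, None], np.where(is_f)[0][None, :]] += config.sex_delta
    lp += rng.normal(0.0, config.noise_sd, size=lp.shape)

    beta = pd.DataFrame(expit(lp), index=pd.Index(probes, name="probe_id"),
                        columns=sheet["sample_id"].to_numpy())
    return beta, sheet, truth


def _draw_serology(group: str, rates: dict, rng: np.random.Generator) -> tuple[str, str]:
    if group == "ra_seropos":
        # rejection sampling until at least one marker is positive
        while True:
            acpa = rng.random() < rates["acpa"]
            rf = rng.random() < rates["rf"]
            if acpa or rf:
                return ("pos" if acpa else "neg", "pos" if rf else "neg")
    # seronegative RA and every non-RA group: both negative
    return "neg", "neg"


def split_by_array(
    beta: pd.DataFrame, sheet: pd.DataFrame, config: SimConfig
) -> list[pd.DataFrame]:
    """Per-array-version submatrices restricted to each version's probe mask.

    Emulates cohorts measured on different array generations; feed the
    result to :func:`methyldx.methio.harmonize_probes`.
    """
    out = []
    for version in sorted(sheet["array_version"].unique()):
        cols = sheet.loc[sheet["array_version"] == version, "sample_id"]
        mask = [p for p in array_mask_probes(config, version) if p in beta.index]
        out.append(beta.loc[mask, cols])
    return out


# ---------------------------------------------------------------------------
# TSV round-trip

_SHEET_COLS = ["sample_id", "group", "age", "sex", "acpa", "rf", "array_version", "split_role"]


def write_cohort(
    beta: pd.DataFrame,
    sheet: pd.DataFrame,
    truth: pd.DataFrame | None,
    directory: str | Path,
) -> dict[str, Path]:
    """Write beta_matrix.tsv, sample_sheet.tsv and (optionally) truth.tsv."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {}
    p = directory / "beta_matrix.tsv"
    beta.to_csv(p, sep="\t", na_rep="NA", index_label="probe_id")
    paths["beta_matrix"] = p
    p = directory / "sample_sheet.tsv"
    sheet.to_csv(p, sep="\t", index=False)
    paths["sample_sheet"] = p
    if truth is not None:
        p = directory / "truth.tsv"
        truth.to_csv(p, sep="\t", index=False)
        paths["truth"] = p
    return paths


def read_cohort(
    directory: str | Path,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame | None]:
    """Read and validate a cohort directory written by :func:`write_cohort`."""
    directory = Path(directory)
    beta = pd.read_csv(directory / "beta_matrix.tsv", sep="\t", index_col=0,
                       na_values=["NA"], keep_default_na=False)
    beta.index.name = "probe_id"
    if beta.index.has_duplicates:
        dup = beta.index[beta.index.duplicated()][0]
        raise ParseError(f"duplicated probe_id {dup!r} in beta_matrix.tsv")
    if beta.columns.has_duplicates:
        dup = beta.columns[beta.columns.duplicated()][0]
        raise ParseError(f"duplicated sample_id {dup!r} in beta_matrix.tsv")
    vals = beta.to_numpy(float)
    bad = (vals < 0) | (vals > 1)
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ParseError(
            f"beta value {vals[i, j]} outside [0,1] at probe "
            f"{beta.index[i]!r}, sample {beta.columns[j]!r}"
        )
    sheet = pd.read_csv(directory / "sample_sheet.tsv", sep="\t",
                        na_values=[""], keep_default_na=False)
    missing_cols = set(_SHEET_COLS) - set(sheet.columns)
    if missing_cols:
        raise ParseError(f"sample_sheet.tsv missing columns {sorted(missing_cols)}")
    truth_path = directory / "truth.tsv"
    truth = None
    if truth_path.exists():
        truth = pd.read_csv(truth_path, sep="\t")
    return beta, sheet, truth
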