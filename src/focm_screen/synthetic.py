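"""Synthetic three-cohort metabolite datasets with planted structure.

Cohort profiles are drawn as correlated Gaussian latents (exchangeable
correlation within blocks), shifted on the standardized latent scale for the
planted discriminative variables, then mapped to positive lognormal
concentrations.  Ratio variables are recomputed exactly from their
components so the collinearity of the real panel is present.  An optional
bounded behavior score is attached to a fraction of the ASD cohort through a
smooth nonlinear link plus noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .data_io import Dataset, Sample
from .panel import PANEL_24, RATIO_COMPONENTS, MetabolitePanel

#: The 20 panel variables that are measured directly (not ratios).
COMPONENT_VARIABLES: tuple[str, ...] = tuple(
    v for v in PANEL_24 if v not in RATIO_COMPONENTS
)


class SyntheticError(ValueError):
    pass


@dataclass(frozen=True)
class VinelandLink:
    """Smooth bounded link from a variable subset to a behavior score.

    score = lo + (hi - lo) * logistic(b0 + b . z + b_int * z_0 * z_1) + noise,
    where z are the standardized latent values of the link variables.
    """

    variables: tuple[str, ...]
    coefficients: tuple[float, ...]
    interaction: float = 0.5
    intercept: float = 0.0
    noise_sd: float = 5.0
    lo: float = 46.0
    hi: float = 106.0
    fraction: float = 55.0 / 83.0

    def __post_init__(self) -> None:
        if len(self.coefficients) != len(self.variables):
            raise SyntheticError("one coefficient per link variable required")
        if not self.lo < self.hi:
            raise SyntheticError("lo must be < hi")
        if not 0 <= self.fraction <= 1:
            raise SyntheticError("fraction must be in [0, 1]")


@dataclass(frozen=True)
class SyntheticConfig:
    n_asd: int = 83
    n_sib: int = 47
    n_neu: int = 76
    variables: tuple[str, ...] = COMPONENT_VARIABLES
    delta: dict = field(default_factory=dict)  # variable -> standardized shift
    sib_mixing: float = 0.15
    block_size: int = 5
    rho: float = 0.3
    cv: float = 0.4  # lognormal coefficient of variation
    base_mean: float = 50.0  # median concentration scale
    vineland_link: VinelandLink | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_asd, self.n_sib, self.n_neu) < 0:
            raise SyntheticError("cohort sizes must be nonnegative")
        if not 0 <= self.sib_mixing <= 1:
            raise SyntheticError("sib_mixing must be in [0, 1]")
        p = len(self.variables)
        if not -1.0 / max(self.block_size - 1, 1) < self.rho < 1.0:
            raise SyntheticError("rho outside the positive-definite range")
        for v in self.delta:
            if v not in self.variables:
                raise SyntheticError(f"delta names unknown variable {v!r}")
        if self.vineland_link is not None:
            for v in self.vineland_link.variables:
                if v not in self.variables:
                    raise SyntheticError(
                        f"vineland link references absent variable {v!r}"
                    )

    @classmethod
    def study_like(cls, seed: int = 0) -> "SyntheticConfig":
        """Default study-mimicking configuration: 83/47/76 cohorts, five
        planted classification variables, five planted regression variables
        with partial overlap."""
        clf_vars = ("% DNA methylation", "8-OHG", "Glu.-Cys.", "fCystine", "GSSG")
        reg_vars = ("GSSG", "Nitrotyrosine", "Tyrosine", "fCysteine", "tGSH")
        return cls(
            delta={v: 1.2 for v in clf_vars},
            vineland_link=VinelandLink(
                variables=reg_vars,
                coefficients=(0.8, -0.8, 0.6, -0.6, 0.5),
            ),
            seed=seed,
        )


@dataclass(frozen=True)
class GroundTruth:
    planted_classification_variables: tuple[str, ...]
    planted_regression_variables: tuple[str, ...]
    delta: dict
    link: VinelandLink | None


def _correlation_cholesky(p: int, block_size: int, rho: float) -> np.ndarray:
    """Cholesky factor of a block-exchangeable correlation matrix."""
    C = np.eye(p)
    for start in range(0, p, block_size):
        stop = min(start + block_size, p)
        C[start:stop, start:stop] = rho
        np.fill_diagonal(C[start:stop, start:stop], 1.0)
    try:
        return np.linalg.cholesky(C)
    except np.linalg.LinAlgError as e:
        raise SyntheticError("invalid correlation structure") from e


def _latents(
    rng: np.random.Generator, n: int, L: np.ndarray, mean_shift: np.ndarray
) -> np.ndarray:
    Z = rng.standard_normal((n, L.shape[0]))
    return Z @ L.T + mean_shift


def generate_cohorts(cfg: SyntheticConfig) -> tuple[Dataset, GroundTruth]:
    """Draw the three cohorts and assemble a panel-aligned Dataset.

    The emitted panel contains the configured component variables plus every
    canonical ratio whose numerator and denominator are both present; ratios
    are exact quotients of the generated components.
    """
    p = len(cfg.variables)
    L = _correlation_cholesky(p, cfg.block_size, cfg.rho)
    delta_vec = np.array([cfg.delta.get(v, 0.0) for v in cfg.variables])
    # ASD shifted by +delta on the latent standardized scale; SIB intermediate
    mu_neu = np.zeros(p)
    mu_asd = delta_vec
    mu_sib = mu_neu + cfg.sib_mixing * (mu_asd - mu_neu)

    rng = np.random.default_rng(cfg.seed)
    blocks = []
    for cohort, n, mu in (
        ("ASD", cfg.n_asd, mu_asd),
        ("SIB", cfg.n_sib, mu_sib),
        ("NEU", cfg.n_neu, mu_neu),
    ):
        Zlat = _latents(rng, n, L, mu)
        blocks.append((cohort, Zlat))

    # lognormal mapping: value = base_mean * exp(s * z - s^2 / 2), median-ish scale
    s = float(np.sqrt(np.log(1.0 + cfg.cv**2)))

    ratios = {
        r: c
        for r, c in RATIO_COMPONENTS.items()
        if c[0] in cfg.variables and c[1] in cfg.variables
    }
    names = list(cfg.variables) + list(ratios)
    panel = MetabolitePanel(names=tuple(names), ratio_components=ratios)

    samples: list[Sample] = []
    latent_by_id: dict[str, np.ndarray] = {}
    counter = 0
    for cohort, Zlat in blocks:
        V = cfg.base_mean * np.exp(s * Zlat - 0.5 * s**2)
        for i in range(Zlat.shape[0]):
            row = list(V[i])
            for r, (num, den) in ratios.items():
                row.append(V[i, names.index(num)] / V[i, names.index(den)])
            sid = f"{cohort}{counter:04d}"
            counter += 1
            samples.append(Sample(id=sid, cohort=cohort, values=np.array(row)))
            latent_by_id[sid] = Zlat[i]

    ds = Dataset(
        panel=panel,
        samples=samples,
        provenance={
            "source": "synthetic",
            "seed": cfg.seed,
            "n": {"ASD": cfg.n_asd, "SIB": cfg.n_sib, "NEU": cfg.n_neu},
            "latents": {k: v.tolist() for k, v in latent_by_id.items()},
        },
    )
    truth = GroundTruth(
        planted_classification_variables=tuple(
            v for v in cfg.variables if cfg.delta.get(v, 0.0) != 0.0
        ),
        planted_regression_variables=(
            cfg.vineland_link.variables if cfg.vineland_link else ()
        ),
        delta=dict(cfg.delta),
        link=cfg.vineland_link,
    )
    return ds, truth


def attach_vineland(ds: Dataset, cfg: SyntheticConfig) -> Dataset:
    """Attach behavior scores to a fraction of the ASD cohort via the link."""
    link = cfg.vineland_link
    if link is None:
        raise SyntheticError("config has no vineland_link")
    if "ASD" not in ds.cohort_counts():
        raise SyntheticError("dataset has no ASD cohort")
    for v in link.variables:
        if v not in ds.panel.names:
            raise SyntheticError(f"link references absent variable {v!r}")
    latents = ds.provenance.get("latents", {})
    var_idx = [cfg.variables.index(v) for v in link.variables]

    rng = np.random.default_rng(cfg.seed + 1)
    asd = [s for s in ds.samples if s.cohort == "ASD"]
    n_with = int(round(link.fraction * len(asd)))
    chosen = set(
        rng.choice(len(asd), size=n_with, replace=False).tolist()
    )
    chosen_ids = {asd[i].id for i in chosen}

    b = np.asarray(link.coefficients)
    new_samples: list[Sample] = []
    for s in ds.samples:
        if s.id not in chosen_ids:
            new_samples.append(s)
            continue
        z = np.asarray(latents[s.id])[var_idx]
        eta = link.intercept + float(b @ z)
        if len(z) >= 2:
            eta += link.interaction * z[0] * z[1]
        base = link.lo + (link.hi - link.lo) / (1.0 + np.exp(-eta))
        score = base + rng.normal(0.0, link.noise_sd)
        score = float(np.clip(score, link.lo, link.hi))
        new_samples.append(replace(s, vineland=score))
    return Dataset(panel=ds.panel, samples=new_samples, provenance=dict(ds.provenance))


def generate_dataset(cfg: SyntheticConfig) -> tuple[Dataset, GroundTruth]:
    """Cohorts plus behavior scores in one call."""
    ds, truth = generate_cohorts(cfg)
    if cfg.vineland_link is not None:
        ds = attach_vineland(ds, cfg)
    return ds, truth
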