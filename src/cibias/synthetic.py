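"""Synthetic isofemale-line fitness datasets.

Emulates the standard isoline fitness assay: a panel of inbred lines (each
treated as one genotype), both sexes measured in several blocks, female
fitness scored as a 7-day adult offspring count and male fitness as the
share of offspring sired in competition against 4 recessive-marker tester
males.  Line effects for the two sexes are drawn from a bivariate normal
with a tunable true intersex correlation ``rho_mf``, so parameter recovery
by the analysis pipeline can be checked against a known truth.

Cytoplasmic incompatibility (CI) can be injected into chosen lines: their
females' expected offspring count collapses (uninfected females mated to
infected males) and their males get a boost on the latent log-odds scale
(uninfected males outcompete infected ones).  A ``cured`` switch turns the
distortion off while reusing the identical underlying random draws, so
cured/uncured worlds are paired by common random numbers and differ only
through the CI effects.

Generated values are shaped like real assay output: female records are
non-negative integers, male records are proportions in [0, 1].
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.special import expit

__all__ = ["IsolineDesign", "generate_dataset", "cure"]


@dataclass(frozen=True)
class IsolineDesign:
    """Design and generative parameters for one synthetic isoline dataset.

    Latent effects (line, block, residual) live on a common unit scale:
    one unit is one log-odds unit for male paternity and ``female_scale``
    offspring for female productivity.

    Parameters
    ----------
    n_lines, n_blocks, n_per_sex_per_block : int
        Assay dimensions; defaults 27 lines x 3 blocks x 10 per sex per
        block (30 individuals/sex/line).
    rho_mf : float
        True intersexual correlation of the line effects, in [-1, 1].
    sigma_line, sigma_block, sigma_resid : float
        SDs of line, block and residual effects on the latent scale.
    female_mean : float
        Expected offspring count of an average infected line's female.
    female_scale : float
        Offspring per latent unit (converts latent effects to counts).
    male_baseline_logit : float
        Baseline log-odds that an offspring is sired by the focal male
        rather than one of the 4 testers (logit(0.2) for even competition).
    n_offspring_assay : int
        Offspring scored per male assay vial.
    ci_lines : tuple of str
        Line ids that are uninfected and hence CI-affected.
    ci_female_mean : float
        Collapsed expected offspring count for CI-line females.
    ci_male_boost : float
        Additive log-odds shift for CI-line males.
    cured : bool
        If True, the infection has been eliminated everywhere: CI effects
        are switched off and ``ci_lines`` only labels line identity.
    seed : int or None
        Seed for the dataset's random stream.
    """

    n_lines: int = 27
    n_blocks: int = 3
    n_per_sex_per_block: int = 10
    rho_mf: float = 0.0
    sigma_line: float = 0.7
    sigma_block: float = 0.3
    sigma_resid: float = 0.8
    female_mean: float = 60.0
    female_scale: float = 15.0
    male_baseline_logit: float = math.log(0.2 / 0.8)
    n_offspring_assay: int = 100
    ci_lines: tuple[str, ...] = ()
    ci_female_mean: float = 5.0
    ci_male_boost: float = 2.0
    cured: bool = False
    seed: int | None = None

    def line_ids(self) -> list[str]:
        width = len(str(self.n_lines))
        return [f"L{i + 1:0{width}d}" for i in range(self.n_lines)]

    def validate(self) -> None:
        for name in ("n_lines", "n_blocks", "n_per_sex_per_block", "n_offspring_assay"):
            v = getattr(self, name)
            if v < 1:
                raise ValueError(f"{name} must be >= 1, got {v}")
        if self.n_lines < 2:
            raise ValueError("need at least 2 lines")
        if not -1.0 <= self.rho_mf <= 1.0:
            raise ValueError(f"rho_mf must be in [-1, 1], got {self.rho_mf}")
        for name in ("sigma_line", "sigma_block", "sigma_resid"):
            v = getattr(self, name)
            if v < 0:
                raise ValueError(f"{name} must be >= 0, got {v}")
        unknown = set(self.ci_lines) - set(self.line_ids())
        if unknown:
            raise ValueError(
                f"ci_lines not in this design's line ids: {sorted(unknown)}"
            )


def generate_dataset(design: IsolineDesign, seed: int | None = None) -> pd.DataFrame:
    """Generate one individual-level fitness dataset.

    Returns a data frame with one row per assayed individual and columns
    ``line_id, sex, block, individual, fitness_raw, infected``; ``sex`` is
    "M"/"F", ``block`` is "B1".., ``infected`` flags the line's original
    infection status (0 for CI lines, 1 otherwise) irrespective of curing.

    All random draws are made unconditionally, in a fixed order that depends
    only on the design's dimensions — never on ``ci_lines`` or ``cured`` —
    so datasets that differ only in those fields are paired by common
    random numbers.

    ``seed`` overrides ``design.seed`` when given.
    """
    design.validate()
    rng = np.random.default_rng(design.seed if seed is None else seed)
    L, B, K = design.n_lines, design.n_blocks, design.n_per_sex_per_block
    n_cells = L * B * K  # records per sex

    # line effects: bivariate normal via Cholesky-style mixing (exact at rho=+/-1)
    u1 = rng.standard_normal(L)
    u2 = rng.standard_normal(L)
    rho = design.rho_mf
    g_male = design.sigma_line * u1
    g_female = design.sigma_line * (rho * u1 + math.sqrt(1.0 - rho * rho) * u2)

    beta = rng.normal(0.0, design.sigma_block, size=B)  # shared by the sexes
    eps_f = rng.normal(0.0, design.sigma_resid, size=n_cells)
    eps_m = rng.normal(0.0, design.sigma_resid, size=n_cells)
    u_pat = rng.uniform(size=n_cells)  # inverse-CDF draws for paternity counts

    line_ids = design.line_ids()
    ci_mask = np.array([lid in design.ci_lines for lid in line_ids])
    ci_active = ci_mask if not design.cured else np.zeros(L, dtype=bool)

    line_idx = np.repeat(np.arange(L), B * K)
    block_idx = np.tile(np.repeat(np.arange(B), K), L)
    indiv = np.tile(np.arange(1, K + 1), L * B)

    # females: offspring counts
    f_mean = np.where(ci_active[line_idx], design.ci_female_mean, design.female_mean)
    latent_f = g_female[line_idx] + beta[block_idx] + eps_f
    f_raw = np.maximum(0.0, np.rint(f_mean + design.female_scale * latent_f))

    # males: paternity share against the testers
    logit = design.male_baseline_logit + g_male[line_idx] + beta[block_idx] + eps_m
    logit = logit + np.where(ci_active[line_idx], design.ci_male_boost, 0.0)
    p_sire = expit(logit)
    wt = sps.binom.ppf(u_pat, design.n_offspring_assay, p_sire)
    m_raw = wt / design.n_offspring_assay

    lid_arr = np.asarray(line_ids, dtype=object)[line_idx]
    blk_arr = np.asarray([f"B{b + 1}" for b in range(B)], dtype=object)[block_idx]
    infected = (~ci_mask[line_idx]).astype(int)

    def sex_frame(sex: str, values: np.ndarray) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "line_id": lid_arr,
                "sex": sex,
                "block": blk_arr,
                "individual": indiv,
                "fitness_raw": values,
                "infected": infected,
            }
        )

    out = pd.concat(
        [sex_frame("F", f_raw), sex_frame("M", m_raw)], ignore_index=True
    )
    return out


def cure(design: IsolineDesign) -> IsolineDesign:
    """Return the design with the infection removed (CI switched off).

    Idempotent; under the same seed the cured dataset reuses the uncured
    dataset's random draws, differing only where CI acted.
    """
    design.validate()
    return replace(design, cured=True)
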