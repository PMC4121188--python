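"""Run configuration and distribution parameters.

Time is measured in minutes and length in nanometres throughout the
package.  The defaults encode the slow-growth (M9/glycerol, 30 C)
conditions of the underlying measurements: per-cell doubling times are
normal with mean 75 min and SD 15 min, and the wild-type division
waiting time (site appearance to division) is normal with mean 17.7 min
and SD 11.9 min.
"""
from __future__ import annotations

from typing import Literal, Optional

from pydantic import BaseModel, ConfigDict, Field, model_validator


class DistParams(BaseModel):
    """Parameters of every stochastic ingredient of the models.

    Attributes
    ----------
    Td_mean, Td_sd:
        Normal distribution of single-cell (compartment) doubling times,
        minutes.
    w_wt_mean, w_wt_sd:
        Wild-type division waiting-time normal, minutes.  Used for both
        site kinds in model 4 and for any WT-strain run.
    w_nonpolar_mean, w_nonpolar_sd:
        minB- non-polar waiting-time normal (models 1-2; model 3 uses it
        for polar sites too), minutes.
    w_polar_mean, w_polar_sd:
        minB- polar waiting-time normal (models 1-2 only), minutes.
    L0_mean, L0_sd:
        Newborn compartment length normal, nm.
    Lc:
        Reference chromosome/compartment size, nm.  Sets the scale of the
        division-machinery competition rate in model 4.
    delta_sd:
        SD of the division-site placement noise, nm.  Placement is
        resampled until the daughter deviates at most 10% from half the
        parent length.
    n_block_target:
        Mean number of blocked potential division sites per cell enforced
        by the re-randomised blocking threshold (the minB- chromosome
        segregation defect).
    c_rate:
        Rate constant of the competition law; calibrated so that a WT
        reference cell (one compartment of length ``Lc``, one active
        site) has unit septum-formation rate.
    """

    model_config = ConfigDict(extra="forbid", validate_assignment=True)

    Td_mean: float = Field(default=75.0, gt=0)
    Td_sd: float = Field(default=15.0, ge=0)
    w_wt_mean: float = Field(default=17.7, gt=0)
    w_wt_sd: float = Field(default=11.9, ge=0)
    w_nonpolar_mean: float = Field(default=25.0, gt=0)
    w_nonpolar_sd: float = Field(default=15.0, ge=0)
    w_polar_mean: float = Field(default=40.0, gt=0)
    w_polar_sd: float = Field(default=20.0, ge=0)
    L0_mean: float = Field(default=2500.0, gt=0)
    L0_sd: float = Field(default=250.0, ge=0)
    Lc: float = Field(default=5000.0, gt=0)
    delta_sd: float = Field(default=100.0, ge=0)
    n_block_target: float = Field(default=2.0, ge=0)
    c_rate: float = Field(default=2.0, gt=0)


class SimConfig(BaseModel):
    """Full configuration of one simulation run.

    ``model_variant`` selects the division-timing model:

    1. waiting times assigned per site kind, no segregation defect;
    2. model 1 plus blocking of potential division sites;
    3. model 2 but polar sites draw from the non-polar distribution;
    4. model 3 but waiting accumulates at a rate set by competition of
       the sites for the division machinery (FtsZ), drawn from the WT
       waiting distribution.
    """

    model_config = ConfigDict(extra="forbid", validate_assignment=True)

    model_variant: Literal[1, 2, 3, 4] = 1
    strain: Literal["WT", "minB"] = "WT"
    ftsz_factor: float = Field(default=1.0, gt=0)
    dt: float = Field(default=1.0, gt=0)
    t_max: float = Field(default=300.0, ge=0)
    n_init: int = Field(default=1000, ge=1)
    rng_seed: int = 0
    dist_params: DistParams = Field(default_factory=DistParams)
    shared_Td: bool = False
    snapshot_every: float = Field(default=10.0, gt=0)
    max_compartments: int = Field(default=1_000_000, ge=1)

    @model_validator(mode="after")
    def _check_horizon(self) -> "SimConfig":
        if 0 < self.t_max < self.dt:
            raise ValueError("t_max must be 0 or at least one time step dt")
        return self
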