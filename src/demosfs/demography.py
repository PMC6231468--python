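"""Four-population divergence/migration model definitions.

The four present-day populations are WAS (Wasatch), EGB (Eastern Great
Basin), PW (Palouse/Wallowa) and WGB (Western Great Basin). Each model
has the same 15 estimated parameters — four present sizes, two
intermediate ancestor sizes (N_1, N_2), three merge times
(T_1 < T_2 < T_3, generations before present) and six pairwise 2Nm
migration rates — plus the fixed ancestral size N_ANC. The three model
topologies:

* Model 1 (tree): (PW, WGB) merge at T_1 (ancestor size N_1);
  (WAS, EGB) merge at T_2 (N_2); the two ancestors join at T_3 (N_ANC).
* Model 2 (stepwise chain, east to west): (WAS, EGB) at T_1 (N_1);
  + PW at T_2 (N_2); + WGB at T_3 (N_ANC).
* Model 3 (stepwise chain, west to east; WAS diverges deepest):
  (PW, WGB) at T_1 (N_1); + EGB at T_2 (N_2); + WAS at T_3 (N_ANC).

Migration is pairwise between geographically adjacent extant
populations only — WAS<->EGB (m_we, m_ew), EGB<->PW (m_ep, m_pe),
PW<->WGB (m_pw, m_wp) — constant while both partners exist and zero
once either has merged into an ancestor. Subscript convention: the
first index is the deme whose lineages move (backward in time), e.g.
m_pw moves PW lineages into WGB; rates are reported as 2*N_first*m.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

POPULATIONS: tuple[str, ...] = ("WAS", "EGB", "PW", "WGB")

SIZE_PARAMS = ("N_WAS", "N_EGB", "N_PW", "N_WGB", "N_1", "N_2")
TIME_PARAMS = ("T_1", "T_2", "T_3")
MIGRATION_PARAMS = ("m_we", "m_ew", "m_ep", "m_pe", "m_pw", "m_wp")
PARAM_NAMES: tuple[str, ...] = SIZE_PARAMS + TIME_PARAMS + MIGRATION_PARAMS

# (source deme, destination deme) of each backward migration, as deme indices
_MIG_ROUTES: dict[str, tuple[int, int]] = {
    "m_we": (0, 1), "m_ew": (1, 0),
    "m_ep": (1, 2), "m_pe": (2, 1),
    "m_pw": (2, 3), "m_wp": (3, 2),
}

# merge schedule per model: (time key, source deme, dest deme, size key)
_MERGES: dict[int, list[tuple[str, int, int, str]]] = {
    1: [("T_1", 3, 2, "N_1"), ("T_2", 1, 0, "N_2"), ("T_3", 0, 2, "N_ANC")],
    2: [("T_1", 1, 0, "N_1"), ("T_2", 2, 0, "N_2"), ("T_3", 3, 0, "N_ANC")],
    3: [("T_1", 3, 2, "N_1"), ("T_2", 1, 2, "N_2"), ("T_3", 0, 2, "N_ANC")],
}


class ModelError(ValueError):
    pass


def ancestral_ne(theta_pi_per_site: float, mu: float, gen_time: float) -> float:
    """Fixed ancestral effective size: N_ANC = theta_pi / 2 / (mu * g)."""
    if theta_pi_per_site <= 0 or mu <= 0 or gen_time <= 0:
        raise ModelError("ancestral_ne inputs must all be positive")
    return theta_pi_per_site / 2.0 / (mu * gen_time)


def scaled_to_raw_migration(two_nm: float, n_deme: float) -> float:
    """Convert a 2Nm-scaled rate to a per-generation per-lineage rate."""
    if n_deme <= 0:
        raise ModelError("deme size must be positive")
    if two_nm < 0:
        raise ModelError("migration rate cannot be negative")
    return two_nm / (2.0 * n_deme)


def raw_to_scaled_migration(m_raw: float, n_deme: float) -> float:
    """Inverse of :func:`scaled_to_raw_migration` (round trip is exact)."""
    if n_deme <= 0:
        raise ModelError("deme size must be positive")
    return m_raw * 2.0 * n_deme


@dataclass
class DemographicModel:
    """One of the three 4-population histories with concrete parameters.

    ``params`` maps every name in :data:`PARAM_NAMES` to its value
    (sizes in diploids, times in generations, migration as 2Nm);
    ``n_anc`` is fixed, never estimated.
    """

    model_id: int
    params: dict[str, float]
    n_anc: float = 60_000.0
    mu: float = 7e-9
    gen_time: float = 1.0

    def __post_init__(self) -> None:
        if self.model_id not in _MERGES:
            raise ModelError(f"unknown model id {self.model_id}")
        missing = [k for k in PARAM_NAMES if k not in self.params]
        if missing:
            raise ModelError(f"missing parameters: {missing}")
        for k in SIZE_PARAMS:
            if self.params[k] <= 0:
                raise ModelError(f"{k} must be positive")
        if self.n_anc <= 0:
            raise ModelError("N_ANC must be positive")
        t1, t2, t3 = (self.params[k] for k in TIME_PARAMS)
        if not (0 < t1 < t2 < t3):
            raise ModelError(f"merge times must satisfy 0 < T_1 < T_2 < T_3, got "
                             f"{t1}, {t2}, {t3}")
        for k in MIGRATION_PARAMS:
            if self.params[k] < 0:
                raise ModelError(f"{k} cannot be negative")

    # -- derived quantities ------------------------------------------------

    def present_sizes(self) -> np.ndarray:
        """Diploid sizes of the four extant demes in POPULATIONS order."""
        return np.array([self.params[f"N_{p}"] for p in POPULATIONS], dtype=float)

    def merge_events(self) -> list[tuple[float, int, int, float]]:
        """(time, source deme, dest deme, new dest size), time-ordered.

        Exactly three events (4 populations -> 3 merges); the last
        installs the fixed ancestral size.
        """
        out = []
        for t_key, src, dst, n_key in _MERGES[self.model_id]:
            size = self.n_anc if n_key == "N_ANC" else self.params[n_key]
            out.append((float(self.params[t_key]), src, dst, float(size)))
        return out

    def migration_matrix(self) -> np.ndarray:
        """Raw backward per-generation lineage migration rates (4x4).

        Entry (i, j): rate at which a lineage in deme i jumps to deme j.
        2Nm is unscaled by the size of the first-subscript (source) deme.
        """
        sizes = self.present_sizes()
        mat = np.zeros((4, 4))
        for key, (src, dst) in _MIG_ROUTES.items():
            mat[src, dst] = scaled_to_raw_migration(self.params[key], sizes[src])
        return mat

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "model_id": self.model_id,
            "params": {k: float(v) for k, v in self.params.items()},
            "n_anc": float(self.n_anc),
            "mu": float(self.mu),
            "gen_time": float(self.gen_time),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DemographicModel":
        return cls(int(d["model_id"]), {k: float(v) for k, v in d["params"].items()},
                   float(d.get("n_anc", 60_000.0)), float(d.get("mu", 7e-9)),
                   float(d.get("gen_time", 1.0)))

    def to_file(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_file(cls, path: str | Path) -> "DemographicModel":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def build_model(model_id: int, params: dict[str, float], *,
                n_anc: float = 60_000.0, mu: float = 7e-9,
                gen_time: float = 1.0) -> DemographicModel:
    """Validated constructor for one of the three model topologies."""
    return DemographicModel(model_id, dict(params), n_anc, mu, gen_time)


#: Point estimates from the best-supported stepwise-chain history
#: (Model 3), used as synthetic ground truth in recovery experiments.
MODEL3_POINT_ESTIMATES: dict[str, float] = {
    "N_1": 8_033.0, "N_2": 3_014.0,
    "N_WAS": 62_936.0, "N_EGB": 45_907.0, "N_PW": 30_800.0, "N_WGB": 10_363.0,
    "T_1": 15_211.0, "T_2": 23_171.0, "T_3": 24_740.0,
    "m_we": 0.46, "m_ew": 0.64, "m_ep": 0.68, "m_pe": 1.02,
    "m_pw": 4.23, "m_wp": 12.57,
}
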