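"""Synthetic ECT study generator with planted causal structure.

Real patient connectomes, seizure EEG, and clinical scores are
access-restricted, so every downstream stage is exercised on a synthetic
cohort that emulates the study design: ~50 depressed patients, binary
structural connectomes, one seizure EEG trace per patient (PSI missing for a
few), and a clinical table with age, sex, and pre/post HDRS.

The planted structural model follows the hypothesized causal chain

    PSI      = a0 + a * z(MC-bar) + e1          (a < 0: low modal
                                                 controllability -> strong
                                                 postictal suppression)
    response = b0 + b * PSI + c' * z(MC-bar)
               + covariate terms + e2           (b < 0 on the signed
                                                 post-minus-pre response:
                                                 high PSI -> improvement)

so the indirect effect a*b is positive on the signed response, matching the
expected direction. Connectomes are small-world graphs whose density varies
across subjects; density drives MC-bar (down) and AC-bar (up), so the
controllability variation is genuinely network-borne, not drawn directly.
EEG traces are synthesized to reproduce each subject's PSI under the
clinical windowing convention.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .connectome import Connectome, default_labels, edge_count, write_connectome
from .controllability import controllability_profile, stabilize
from .psi import EEGTrace, write_eeg

__all__ = [
    "SyntheticConfig",
    "SyntheticCohort",
    "generate_connectome",
    "generate_eeg",
    "generate_cohort",
]

# Oscillatory components of the synthetic ictal EEG: frequencies are integer
# numbers of cycles per 1.28 s analysis window so window power is phase-exact.
_EEG_CYCLES_PER_WINDOW = (6, 13, 24)
_EEG_AMPLITUDES_UV = (60.0, 40.0, 25.0)
# noise level calibrated so the signal-noise cross term in the 3x1.28 s
# window power estimates keeps the PSI round-trip error well inside 0.02
_EEG_NOISE_SD_UV = 1.5


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the planted study; defaults are the reference conditions.

    Effect sizes are chosen to put the partial eta-squared of the main
    contrasts in the 0.05-0.15 band at n = 50. ``path_a_mc`` is in PSI units
    per SD of MC-bar; ``path_b`` in HDRS points per unit PSI; ``direct_c_mc``
    in HDRS points per SD of MC-bar.
    """

    n_subjects: int = 50
    n_nodes: int = 100
    psi_missing_count: int = 5
    # structural (causal) paths
    path_a_mc: float = -0.06
    path_b: float = -18.0
    direct_c_mc: float = 2.0
    psi_intercept: float = 0.70
    psi_noise_sd: float = 0.15
    response_intercept: float = -12.0
    response_noise_sd: float = 7.0
    # covariate effects on response
    age_effect: float = 0.08
    sex_effect: float = 1.0
    baseline_effect: float = -0.15
    # demographics (age and the 29/50 female split follow the study sample)
    age_mean: float = 45.1
    age_sd: float = 10.8
    female_prob: float = 29.0 / 50.0
    hdrs_pre_mean: float = 25.0
    hdrs_pre_sd: float = 5.0
    # connectome generator
    density_range: tuple[float, float] = (0.10, 0.35)
    rewiring: float = 0.1
    hub_strength_range: tuple[float, float] = (0.0, 0.5)
    n_hubs: int = 5
    # EEG generator
    eeg_fs: float = 200.0
    eeg_phase_seconds: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1 or self.n_nodes < 2:
            raise ValueError("counts must be positive")
        if not (0 <= self.psi_missing_count < self.n_subjects):
            raise ValueError("psi_missing_count must be < n_subjects")
        lo, hi = self.density_range
        if not (0.0 < lo <= hi < 1.0):
            raise ValueError("density_range must lie inside (0, 1)")
        hlo, hhi = self.hub_strength_range
        if not (0.0 <= hlo <= hhi < 1.0):
            raise ValueError("hub_strength_range must lie inside [0, 1)")
        if self.psi_noise_sd < 0 or self.response_noise_sd < 0:
            raise ValueError("noise SDs must be nonnegative")


@dataclass(frozen=True)
class SyntheticCohort:
    """A generated study: clinical table, per-subject networks and EEG."""

    table: pd.DataFrame
    connectomes: dict[str, Connectome]
    eeg: dict[str, EEGTrace]
    ground_truth: dict


def generate_connectome(
    n_nodes: int,
    density: float,
    rewiring: float = 0.1,
    seed: int = 0,
    hub_strength: float = 0.0,
    n_hubs: int = 5,
) -> Connectome:
    """Binary small-world connectome with an exact density-derived edge count.

    A connected Watts-Strogatz ring lattice (largest even degree fitting the
    target) is rewired with probability ``rewiring``, then random absent
    edges are added until the edge count equals ``round(density * n(n-1)/2)``.
    ``hub_strength`` then moves that fraction of hub-free edges onto
    ``n_hubs`` randomly chosen hub regions, emulating inter-individual
    variation in hub organization: it raises the adjacency's top eigenvalue
    (hence whole-brain controllability structure) at *fixed* edge count.
    The graph is kept connected by re-drawing; deterministic given ``seed``.
    """
    if not (0.0 < density < 1.0):
        raise ValueError("density must lie in (0, 1)")
    if not (0.0 <= hub_strength < 1.0):
        raise ValueError("hub_strength must lie in [0, 1)")
    m_max = n_nodes * (n_nodes - 1) // 2
    m_target = int(round(density * m_max))
    if m_target < n_nodes or m_target > m_max:
        raise ValueError(
            f"infeasible density {density}: target {m_target} edges for "
            f"{n_nodes} nodes (need between {n_nodes} and {m_max})"
        )
    k = 2 * (m_target // n_nodes)
    k = min(k, n_nodes - 1 - (n_nodes % 2 == 0))  # keep k < n
    rng = np.random.default_rng(seed)
    for _attempt in range(50):
        g = nx.connected_watts_strogatz_graph(
            n_nodes, k, rewiring, tries=200, seed=int(rng.integers(2**31))
        )
        adj = nx.to_numpy_array(g, nodelist=range(n_nodes))
        iu, ju = np.triu_indices(n_nodes, k=1)
        absent = np.flatnonzero(adj[iu, ju] == 0)
        deficit = m_target - g.number_of_edges()
        if deficit < 0:  # cannot happen with k = floor-even, kept as a guard
            raise RuntimeError("lattice exceeded the target edge count")
        add = rng.choice(absent, size=deficit, replace=False)
        adj[iu[add], ju[add]] = 1.0
        adj[ju[add], iu[add]] = 1.0
        if hub_strength > 0.0 and n_hubs > 0:
            _concentrate_hubs(adj, hub_strength, n_hubs, rng)
        n_comp = nx.number_connected_components(nx.from_numpy_array(adj))
        if n_comp == 1:
            return Connectome(default_labels(n_nodes), adj, is_binary=True)
    raise RuntimeError("could not draw a connected graph in 50 attempts")


def _concentrate_hubs(
    adj: np.ndarray, hub_strength: float, n_hubs: int, rng: np.random.Generator
) -> None:
    """Move a fraction of hub-free edges onto hub nodes, in place.

    Each moved edge (u, v) with neither endpoint a hub becomes (u, h) for a
    random hub h not already adjacent to u, so the edge count is preserved
    while hub degrees grow.
    """
    n = adj.shape[0]
    hubs = rng.choice(n, size=min(n_hubs, n), replace=False)
    hub_mask = np.zeros(n, dtype=bool)
    hub_mask[hubs] = True
    ei, ej = np.nonzero(np.triu(adj, 1))
    free = np.flatnonzero(~hub_mask[ei] & ~hub_mask[ej])
    n_move = int(round(hub_strength * free.size))
    moved = 0
    for t in rng.permutation(free):
        if moved >= n_move:
            break
        u, v = int(ei[t]), int(ej[t])
        h = int(hubs[rng.integers(len(hubs))])
        if adj[u, h] == 0 and u != h:
            adj[u, v] = adj[v, u] = 0.0
            adj[u, h] = adj[h, u] = 1.0
            moved += 1


def generate_eeg(
    psi_target: float,
    fs: float = 200.0,
    phase_seconds: float = 20.0,
    seed: int = 0,
) -> EEGTrace:
    """Synthesize a seizure EEG trace whose PSI equals ``psi_target``.

    The seizure phase is a polyspike-like mixture of three oscillations plus
    Gaussian noise; the termination phase is the same process with overall
    amplitude scaled by ``sqrt(1 - psi_target)`` (postictal flattening
    suppresses the whole signal). The clinical windowing then recovers
    ``psi_target`` to within ~0.01.
    """
    if not (0.0 <= psi_target < 1.0):
        raise ValueError("psi_target must lie in [0, 1)")
    win_seconds = 1.28
    min_phase = 3 * win_seconds + 1.92
    if phase_seconds < min_phase:
        raise ValueError(
            f"phase_seconds {phase_seconds} too short; need >= {min_phase}"
        )
    rng = np.random.default_rng(seed)
    n_phase = int(round(phase_seconds * fs))
    t = np.arange(n_phase) / fs
    freqs = [k / win_seconds for k in _EEG_CYCLES_PER_WINDOW]

    def phase_signal() -> np.ndarray:
        x = np.zeros(n_phase)
        for a, f in zip(_EEG_AMPLITUDES_UV, freqs):
            x += a * np.sin(2.0 * np.pi * f * t + rng.uniform(0, 2 * np.pi))
        return x + rng.normal(0.0, _EEG_NOISE_SD_UV, size=n_phase)

    seizure = phase_signal()
    termination = np.sqrt(1.0 - psi_target) * phase_signal()
    samples = np.concatenate([seizure, termination])
    return EEGTrace(samples=samples, sampling_rate=fs, seizure_end_index=n_phase)


def _z(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=0)
    if sd == 0:
        raise ValueError("zero variance; cannot standardize")
    return (x - x.mean()) / sd


def generate_cohort(
    config: SyntheticConfig = SyntheticConfig(),
    out_dir: str | Path | None = None,
    include_eeg: bool = True,
) -> SyntheticCohort:
    """Generate the full synthetic study from the planted structural model.

    Connectomes are drawn first and their true AC-bar/MC-bar computed through
    the controllability pipeline; PSI and treatment response then follow the
    structural equations; EEG traces are synthesized to match each subject's
    PSI. Exactly ``psi_missing_count`` subjects lack a recorded PSI (their
    latent seizure quality still drives their response). Fully reproducible
    given ``config.seed``.

    When ``out_dir`` is given, writes ``cohort.csv``, one connectome TSV and
    one EEG CSV+JSON per subject, and ``ground_truth.json``.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    ids = [f"sub-{i + 1:03d}" for i in range(cfg.n_subjects)]

    densities = rng.uniform(*cfg.density_range, size=cfg.n_subjects)
    hub_strengths = rng.uniform(*cfg.hub_strength_range, size=cfg.n_subjects)
    connectomes: dict[str, Connectome] = {}
    ac_mean = np.empty(cfg.n_subjects)
    mc_mean = np.empty(cfg.n_subjects)
    edges = np.empty(cfg.n_subjects, dtype=int)
    for i, sid in enumerate(ids):
        c = generate_connectome(
            cfg.n_nodes,
            densities[i],
            cfg.rewiring,
            seed=int(rng.integers(2**31)),
            hub_strength=hub_strengths[i],
            n_hubs=cfg.n_hubs,
        )
        prof = controllability_profile(stabilize(c))
        connectomes[sid] = c
        ac_mean[i], mc_mean[i] = prof.ac_mean, prof.mc_mean
        edges[i] = edge_count(c)

    age = np.clip(rng.normal(cfg.age_mean, cfg.age_sd, cfg.n_subjects), 18, 80)
    sex = (rng.random(cfg.n_subjects) < cfg.female_prob).astype(int)  # 1 = female
    hdrs_pre = np.clip(
        rng.normal(cfg.hdrs_pre_mean, cfg.hdrs_pre_sd, cfg.n_subjects), 8, None
    )

    z_mc = _z(mc_mean)
    psi_true = np.clip(
        cfg.psi_intercept
        + cfg.path_a_mc * z_mc
        + rng.normal(0.0, cfg.psi_noise_sd, cfg.n_subjects),
        0.0,
        0.999,
    )
    response = (
        cfg.response_intercept
        + cfg.path_b * psi_true
        + cfg.direct_c_mc * z_mc
        + cfg.age_effect * (age - cfg.age_mean)
        + cfg.sex_effect * sex
        + cfg.baseline_effect * (hdrs_pre - cfg.hdrs_pre_mean)
        + rng.normal(0.0, cfg.response_noise_sd, cfg.n_subjects)
    )
    hdrs_post = hdrs_pre + response

    missing_idx = rng.choice(cfg.n_subjects, size=cfg.psi_missing_count, replace=False)
    psi_obs = psi_true.copy()
    psi_obs[missing_idx] = np.nan

    eeg: dict[str, EEGTrace] = {}
    if include_eeg:
        for i, sid in enumerate(ids):
            if np.isnan(psi_obs[i]):
                continue
            eeg[sid] = generate_eeg(
                float(psi_true[i]),
                fs=cfg.eeg_fs,
                phase_seconds=cfg.eeg_phase_seconds,
                seed=int(rng.integers(2**31)),
            )

    table = pd.DataFrame(
        {
            "id": ids,
            "age": age,
            "sex": sex,
            "hdrs_pre": hdrs_pre,
            "hdrs_post": hdrs_post,
            "response": response,
            "edge_count": edges,
            "ac_mean": ac_mean,
            "mc_mean": mc_mean,
            "psi": psi_obs,
        }
    )
    ground_truth = {
        "path_a_mc": cfg.path_a_mc,
        "path_b": cfg.path_b,
        "indirect_ab": cfg.path_a_mc * cfg.path_b,
        "direct_c_mc": cfg.direct_c_mc,
        "total_c_mc": cfg.direct_c_mc + cfg.path_a_mc * cfg.path_b,
        "psi_true": psi_true.tolist(),
        "missing_psi_ids": [ids[j] for j in sorted(missing_idx)],
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in asdict(cfg).items()
        },
    }

    if out_dir is not None:
        out = Path(out_dir)
        (out / "connectomes").mkdir(parents=True, exist_ok=True)
        (out / "eeg").mkdir(parents=True, exist_ok=True)
        table.to_csv(out / "cohort.csv", index=False)
        for sid, c in connectomes.items():
            write_connectome(c, out / "connectomes" / f"{sid}.tsv")
        for sid, tr in eeg.items():
            write_eeg(tr, out / "eeg" / f"{sid}.csv")
        (out / "ground_truth.json").write_text(
            json.dumps(ground_truth, indent=2, sort_keys=True) + "\n"
        )

    return SyntheticCohort(
        table=table, connectomes=connectomes, eeg=eeg, ground_truth=ground_truth
    )
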