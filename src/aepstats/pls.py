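"""Task partial least squares (PLS) on spatiotemporal evoked-potential
matrices: mean-centered (exploratory) and non-rotated (hypothesis-driven)
variants, with permutation tests for latent-variable significance and
bootstrap ratios for salience stability.

The data matrix stacks subjects by condition (group x session); columns
are (electrode, latency) pairs over the 0-300 ms window.  Mean-centered
PLS computes the SVD of the condition-mean deviation matrix via its small
conditions x conditions cross-product, so the feature dimension is never
materialized beyond one matrix.  Non-rotated PLS projects the centered
condition means onto a single a-priori contrast (default (-1, 0, 1) over
sessions), yielding exactly one latent variable.

Resampling respects the repeated-measures structure: permutations shuffle
session labels within subject and whole subjects across groups; bootstrap
draws resample subjects with replacement within group, keeping each
subject's session rows together.  The p-value convention is
(b + 1)/(n + 1).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import Evoked
from .errors import ConfigError, DesignError
from .montage import Montage

__all__ = ["PlsDataMatrix", "PlsDesign", "TaskPLS", "TaskPLSResults",
           "assemble_data_matrix", "mean_center_conditions",
           "fit_mc_pls", "fit_nr_pls", "permutation_test",
           "bootstrap_stability", "DEFAULT_PLS_WINDOW"]

DEFAULT_PLS_WINDOW = (0.0, 300.0)
DEFAULT_BSR_THRESHOLD = 3.0


# ---------------------------------------------------------------------------
# data matrix
# ---------------------------------------------------------------------------

@dataclass
class PlsDataMatrix:
    """Rows = subject x condition observations (grouped contiguously by
    condition in a fixed (group, session) order); columns = electrode-major
    (electrode, latency ms) pairs."""

    X: np.ndarray
    rows: pd.DataFrame                    # subject, group, session
    electrodes: list[str]
    latencies: np.ndarray
    stimulus: str | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.latencies = np.asarray(self.latencies, dtype=float)
        if self.X.shape[0] != len(self.rows):
            raise DesignError("row index length does not match matrix")
        if self.X.shape[1] != len(self.electrodes) * len(self.latencies):
            raise DesignError("column count != n_electrodes x n_latencies")

    @property
    def conditions(self) -> list[tuple[int, int]]:
        seen: list[tuple[int, int]] = []
        for g, s in zip(self.rows["group"], self.rows["session"]):
            if (g, s) not in seen:
                seen.append((int(g), int(s)))
        return seen

    @property
    def n_conditions(self) -> int:
        return len(self.conditions)

    def col_index(self, electrode: str, latency: float) -> int:
        e = self.electrodes.index(electrode)
        t = int(np.flatnonzero(np.isclose(self.latencies, latency))[0])
        return e * len(self.latencies) + t

    def column_frame(self) -> pd.DataFrame:
        """(electrode, latency) label per column, in column order."""
        return pd.DataFrame({
            "electrode": np.repeat(self.electrodes, len(self.latencies)),
            "latency": np.tile(self.latencies, len(self.electrodes)),
        })

    def condition_row_indices(self) -> dict[tuple[int, int], np.ndarray]:
        out = {}
        for cond in self.conditions:
            mask = ((self.rows["group"] == cond[0])
                    & (self.rows["session"] == cond[1])).to_numpy()
            out[cond] = np.flatnonzero(mask)
        return out


def assemble_data_matrix(evokeds: dict[tuple, Evoked], montage: Montage,
                         window: tuple[float, float] = DEFAULT_PLS_WINDOW,
                         decimate: int = 1) -> PlsDataMatrix:
    """Stack scalp-electrode evoked segments into the PLS data matrix.

    All evokeds must share one stimulus (amplitude-latency differences
    between stimuli would masquerade as effects), montage and time axis.
    ``decimate`` keeps every n-th sample in the window (coarser temporal
    grid for Monte-Carlo calibration studies).
    """
    if not evokeds:
        raise DesignError("no evokeds supplied")
    stimuli = {k[3] for k in evokeds}
    if len(stimuli) > 1:
        raise DesignError(f"mixed stimuli in one matrix: {sorted(stimuli)}")
    keys = sorted(evokeds.keys(), key=lambda k: (k[1], k[2], k[0]))
    first = evokeds[keys[0]]
    mask = first.time_mask(window)
    if decimate > 1:
        sub = np.zeros_like(mask)
        sub[np.flatnonzero(mask)[::decimate]] = True
        mask = sub
    latencies = first.times[mask]
    scalp = [c for c in first.channels if c in set(montage.scalp_labels)]
    rows, X = [], []
    for key in keys:
        ev = evokeds[key]
        if list(ev.times) != list(first.times):
            raise DesignError("evokeds must share one time axis")
        idx = [ev.channel_index(c) for c in scalp]
        X.append(ev.data[np.ix_(idx, mask)].reshape(-1))
        rows.append(dict(subject=ev.subject, group=ev.group, session=ev.session))
    return PlsDataMatrix(X=np.array(X), rows=pd.DataFrame(rows),
                         electrodes=scalp, latencies=latencies,
                         stimulus=keys[0][3])


def mean_center_conditions(data: PlsDataMatrix) -> np.ndarray:
    """Condition means minus the grand mean of condition means
    (conditions x columns); rows sum to the zero vector."""
    cond_rows = data.condition_row_indices()
    if len(cond_rows) < 2:
        raise DesignError("need at least 2 conditions to mean-center")
    means = []
    for cond, idx in cond_rows.items():
        if len(idx) == 0:
            raise DesignError(f"empty condition cell {cond}")
        means.append(data.X[idx].mean(axis=0))
    M = np.array(means)
    return M - M.mean(axis=0, keepdims=True)


# ---------------------------------------------------------------------------
# design
# ---------------------------------------------------------------------------

@dataclass
class PlsDesign:
    """kind 'mean_centering' or 'non_rotated'; for the latter, one contrast
    weight per condition (zero-sum; unit-normalized internally)."""

    kind: str
    contrast: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("mean_centering", "non_rotated"):
            raise DesignError(f"unknown PLS kind {self.kind!r}")
        if self.kind == "non_rotated":
            if self.contrast is None:
                raise DesignError("non-rotated PLS requires a contrast")
            self.contrast = np.asarray(self.contrast, dtype=float)
            if abs(self.contrast.sum()) > 1e-9:
                raise DesignError("contrast must sum to 0")
            if np.linalg.norm(self.contrast) == 0:
                raise DesignError("contrast must be nonzero")


# ---------------------------------------------------------------------------
# results
# ---------------------------------------------------------------------------

@dataclass
class TaskPLSResults:
    """Latent variables of one task-PLS fit.

    singular_values: s_k >= 0 (descending for mean-centering).
    design_saliencies: conditions x LVs (orthonormal for MC; the normalized
        contrast for NR).
    electrode_saliencies: columns x LVs, unit-norm per LV (zero for
        degenerate LVs).
    covariance_fractions: s_k^2 / sum s^2 (share of cross-block covariance).
    subject_scores: rows x LVs projections of the raw data.
    perm_p: permutation p per LV, (b+1)/(n+1) convention; None if not run.
    bootstrap_ratios: columns x LVs salience / bootstrap SE; None if not run.
    """

    kind: str
    conditions: list[tuple[int, int]]
    singular_values: np.ndarray
    design_saliencies: np.ndarray
    electrode_saliencies: np.ndarray
    covariance_fractions: np.ndarray
    subject_scores: np.ndarray
    column_index: pd.DataFrame
    stimulus: str | None = None
    perm_p: np.ndarray | None = None
    n_perm: int = 0
    bootstrap_ratios: np.ndarray | None = None
    n_boot: int = 0
    bsr_threshold: float = DEFAULT_BSR_THRESHOLD
    degenerate: bool = False
    seed: int | None = None
    boot_redraws: int = 0

    @property
    def n_latent_variables(self) -> int:
        return len(self.singular_values)

    @property
    def stable_mask(self) -> np.ndarray | None:
        if self.bootstrap_ratios is None:
            return None
        return np.abs(self.bootstrap_ratios) > self.bsr_threshold

    def salience_table(self, lv: int = 0) -> pd.DataFrame:
        tab = self.column_index.copy()
        tab["salience"] = self.electrode_saliencies[:, lv]
        if self.bootstrap_ratios is not None:
            tab["bootstrap_ratio"] = self.bootstrap_ratios[:, lv]
            tab["stable"] = self.stable_mask[:, lv]
        return tab

    def summary(self) -> str:
        lines = [f"Task-PLS ({self.kind})"
                 + (f", stimulus={self.stimulus}" if self.stimulus else ""),
                 f"conditions (group, session): {self.conditions}",
                 f"{'LV':>3} {'singular':>12} {'cov %':>8} {'perm p':>10}"]
        for k, s in enumerate(self.singular_values):
            p = f"{self.perm_p[k]:.4f}" if self.perm_p is not None else "-"
            lines.append(f"{k + 1:>3} {s:>12.4f} "
                         f"{100 * self.covariance_fractions[k]:>8.2f} {p:>10}")
        if self.bootstrap_ratios is not None:
            n_stable = int(self.stable_mask[:, 0].sum())
            lines.append(f"LV1 stable columns (|BSR| > {self.bsr_threshold:g}): "
                         f"{n_stable} / {self.bootstrap_ratios.shape[0]}")
        if self.degenerate:
            lines.append("fit flagged degenerate (all singular values 0)")
        return "\n".join(lines)

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "conditions": [list(c) for c in self.conditions],
            "stimulus": self.stimulus,
            "singular_values": self.singular_values.tolist(),
            "design_saliencies": self.design_saliencies.tolist(),
            "electrode_saliencies": self.electrode_saliencies.tolist(),
            "covariance_fractions": self.covariance_fractions.tolist(),
            "subject_scores": self.subject_scores.tolist(),
            "column_electrode": self.column_index["electrode"].tolist(),
            "column_latency": self.column_index["latency"].tolist(),
            "perm_p": None if self.perm_p is None else self.perm_p.tolist(),
            "n_perm": self.n_perm,
            "bootstrap_ratios": (None if self.bootstrap_ratios is None
                                 else self.bootstrap_ratios.tolist()),
            "n_boot": self.n_boot,
            "bsr_threshold": self.bsr_threshold,
            "degenerate": self.degenerate,
            "seed": self.seed,
            "boot_redraws": self.boot_redraws,
        }

    def save_json(self, path) -> None:
        with open(path, "w") as f:
            json.dump(self.to_dict(), f, sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict) -> "TaskPLSResults":
        col = pd.DataFrame({"electrode": d["column_electrode"],
                            "latency": d["column_latency"]})
        return cls(
            kind=d["kind"], conditions=[tuple(c) for c in d["conditions"]],
            singular_values=np.array(d["singular_values"]),
            design_saliencies=np.array(d["design_saliencies"]),
            electrode_saliencies=np.array(d["electrode_saliencies"]),
            covariance_fractions=np.array(d["covariance_fractions"]),
            subject_scores=np.array(d["subject_scores"]),
            column_index=col, stimulus=d["stimulus"],
            perm_p=None if d["perm_p"] is None else np.array(d["perm_p"]),
            n_perm=d["n_perm"],
            bootstrap_ratios=(None if d["bootstrap_ratios"] is None
                              else np.array(d["bootstrap_ratios"])),
            n_boot=d["n_boot"], bsr_threshold=d["bsr_threshold"],
            degenerate=d["degenerate"], seed=d["seed"],
            boot_redraws=d["boot_redraws"])

    @classmethod
    def load_json(cls, path) -> "TaskPLSResults":
        with open(path) as f:
            return cls.from_dict(json.load(f))


# ---------------------------------------------------------------------------
# model
# ---------------------------------------------------------------------------

class TaskPLS:
    """Task-PLS model over a :class:`PlsDataMatrix` and a :class:`PlsDesign`.

    ``fit`` computes the decomposition and, when requested, the permutation
    and bootstrap inference, returning :class:`TaskPLSResults`.
    """

    def __init__(self, data: PlsDataMatrix, design: PlsDesign):
        if data.X.shape[0] < data.n_conditions:
            raise DesignError("fewer rows than conditions")
        if (design.kind == "non_rotated"
                and len(design.contrast) != data.n_conditions):
            raise DesignError(
                f"contrast length {len(design.contrast)} != "
                f"{data.n_conditions} conditions")
        self.data = data
        self.design = design
        self._build_structure()

    def _build_structure(self) -> None:
        """Cache row structure as plain arrays for the resampling loops."""
        rows = self.data.rows
        conds = self.data.conditions
        self._cond_lut = {c: i for i, c in enumerate(conds)}
        self._subjects = rows["subject"].unique().tolist()
        subj_codes = rows["subject"].map(
            {s: i for i, s in enumerate(self._subjects)}).to_numpy()
        self._subj_rows = [np.flatnonzero(subj_codes == i)
                           for i in range(len(self._subjects))]
        groups = rows["group"].to_numpy()
        sessions = rows["session"].to_numpy()
        self._subj_groups = np.array([int(groups[r[0]])
                                      for r in self._subj_rows])
        self._sessions_by_subj = [sessions[r].astype(int)
                                  for r in self._subj_rows]
        self._assign0 = np.array([self._cond_lut[(int(g), int(s))]
                                  for g, s in zip(groups, sessions)])

    # -- decomposition -----------------------------------------------------
    def _decompose(self, M: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(s, U, V) with M = sum_k s_k u_k v_k^T; the SVD runs on the
        small conditions x conditions cross-product."""
        if self.design.kind == "mean_centering":
            G = M @ M.T
            lam, U = np.linalg.eigh(G)
            order = np.argsort(lam)[::-1]
            lam, U = np.clip(lam[order], 0.0, None), U[:, order]
            # numerically-null eigenvalues are exact zeros (rank deficiency
            # from mean-centering), not sqrt(eps) artifacts
            if lam[0] > 0:
                lam[lam < lam[0] * 1e-12] = 0.0
            s = np.sqrt(lam)
            V = np.zeros((M.shape[1], len(s)))
            nz = s > (s[0] * 1e-12 if s[0] > 0 else 0)
            if nz.any():
                V[:, nz] = M.T @ U[:, nz] / s[nz]
            # deterministic sign: largest-|u| element positive
            for k in range(len(s)):
                i = int(np.argmax(np.abs(U[:, k])))
                if U[i, k] < 0:
                    U[:, k] *= -1
                    V[:, k] *= -1
            return s, U, V
        c = self.design.contrast / np.linalg.norm(self.design.contrast)
        v_raw = M.T @ c
        s = np.linalg.norm(v_raw)
        V = (v_raw / s if s > 0 else np.zeros_like(v_raw))[:, None]
        return np.array([s]), c[:, None], V

    # -- resampling machinery ----------------------------------------------
    def _means_for_assignment(self, assign: np.ndarray) -> np.ndarray:
        X = self.data.X
        M = np.empty((self.data.n_conditions, X.shape[1]))
        for c in range(self.data.n_conditions):
            idx = np.flatnonzero(assign == c)
            if len(idx) == 0:
                raise DesignError("empty condition cell")
            M[c] = X[idx].mean(axis=0)
        return M - M.mean(axis=0, keepdims=True)

    def _permuted_assignment(self, rng: np.random.Generator) -> np.ndarray:
        """Restricted permutation: session labels shuffled within subject,
        whole subjects shuffled across groups."""
        perm_groups = rng.permutation(self._subj_groups)
        assign = np.empty(len(self.data.rows), dtype=int)
        lut = self._cond_lut
        for s_i in range(len(self._subjects)):
            perm_sess = rng.permutation(self._sessions_by_subj[s_i])
            g = int(perm_groups[s_i])
            rows_i = self._subj_rows[s_i]
            for r, ses in zip(rows_i, perm_sess):
                assign[r] = lut[(g, int(ses))]
        return assign

    # -- fitting -----------------------------------------------------------
    def fit(self, n_perm: int = 0, n_boot: int = 0,
            seed: int | None = None,
            bsr_threshold: float = DEFAULT_BSR_THRESHOLD) -> TaskPLSResults:
        M = self._means_for_assignment(self._assign0)
        s, U, V = self._decompose(M)
        total = float((s ** 2).sum())
        fractions = s ** 2 / total if total > 0 else np.zeros_like(s)
        degenerate = total == 0.0
        scores = self.data.X @ V
        res = TaskPLSResults(
            kind=self.design.kind, conditions=self.data.conditions,
            singular_values=s, design_saliencies=U, electrode_saliencies=V,
            covariance_fractions=fractions, subject_scores=scores,
            column_index=self.data.column_frame(), stimulus=self.data.stimulus,
            bsr_threshold=bsr_threshold, degenerate=degenerate, seed=seed)
        root = np.random.SeedSequence(seed)
        perm_seq, boot_seq = root.spawn(2)
        if n_perm:
            res.perm_p = self._permutation(s, n_perm,
                                           np.random.default_rng(perm_seq))
            res.n_perm = n_perm
        if n_boot:
            res.bootstrap_ratios, res.boot_redraws = self._bootstrap(
                V, s, n_boot, np.random.default_rng(boot_seq))
            res.n_boot = n_boot
        return res

    def _permutation(self, s_obs: np.ndarray, n_perm: int,
                     rng: np.random.Generator) -> np.ndarray:
        if n_perm < 1:
            raise ConfigError("n_perm must be >= 1")
        count = np.zeros_like(s_obs)
        for _ in range(n_perm):
            Mp = self._means_for_assignment(self._permuted_assignment(rng))
            sp, _, _ = self._decompose(Mp)
            count += sp >= s_obs - 1e-12
        return (count + 1.0) / (n_perm + 1.0)

    def _bootstrap(self, V: np.ndarray, s: np.ndarray, n_boot: int,
                   rng: np.random.Generator) -> tuple[np.ndarray, int]:
        """Bootstrap ratios on the singular-value-weighted saliencies
        (salience x s), the scale on which saliencies are reported."""
        if n_boot < 1:
            raise ConfigError("n_boot must be >= 1")
        by_group: dict[int, list[int]] = {}
        for s_i, g in enumerate(self._subj_groups):
            by_group.setdefault(int(g), []).append(s_i)
        assign0 = self._assign0
        subj_rows = self._subj_rows
        n_cols, n_lv = V.shape
        acc = np.zeros((n_cols, n_lv))
        acc2 = np.zeros((n_cols, n_lv))
        redraws = 0
        for _ in range(n_boot):
            for _attempt in range(100):
                rows_idx, assign = [], []
                for g, members in by_group.items():
                    draw = rng.integers(0, len(members), size=len(members))
                    for j in draw:
                        s_i = members[j]
                        rows_idx.extend(subj_rows[s_i])
                        assign.extend(assign0[subj_rows[s_i]])
                assign = np.asarray(assign)
                if len(np.unique(assign)) == self.data.n_conditions:
                    break
                redraws += 1       # a condition cell came up empty; redraw
            Xb = self.data.X[np.asarray(rows_idx)]
            Mb = np.empty((self.data.n_conditions, n_cols))
            for c in range(self.data.n_conditions):
                Mb[c] = Xb[assign == c].mean(axis=0)
            Mb -= Mb.mean(axis=0, keepdims=True)
            sb, Ub, Vb = self._decompose(Mb)
            # sign-align each refit LV to the original saliencies
            flips = np.sign(np.einsum("ck,ck->k", Vb, V))
            flips[flips == 0] = 1.0
            Wb = Vb * (flips * sb)
            acc += Wb
            acc2 += Wb ** 2
        mean = acc / n_boot
        var = np.maximum(acc2 / n_boot - mean ** 2, 0.0)
        sd = np.sqrt(var * n_boot / max(n_boot - 1, 1))
        W = V * s
        with np.errstate(divide="ignore", invalid="ignore"):
            bsr = W / sd
        bsr[(sd == 0) & (W == 0)] = 0.0
        bsr[(sd == 0) & (W != 0)] = np.inf * np.sign(W[(sd == 0) & (W != 0)])
        return bsr, redraws


# ---------------------------------------------------------------------------
# functional surface
# ---------------------------------------------------------------------------

def fit_mc_pls(data: PlsDataMatrix, n_perm: int = 0, n_boot: int = 0,
               seed: int | None = None,
               bsr_threshold: float = DEFAULT_BSR_THRESHOLD) -> TaskPLSResults:
    """Mean-centered task-PLS; one LV per condition."""
    return TaskPLS(data, PlsDesign("mean_centering")).fit(
        n_perm=n_perm, n_boot=n_boot, seed=seed, bsr_threshold=bsr_threshold)


def fit_nr_pls(data: PlsDataMatrix, contrast=(-1.0, 0.0, 1.0),
               n_perm: int = 0, n_boot: int = 0, seed: int | None = None,
               bsr_threshold: float = DEFAULT_BSR_THRESHOLD) -> TaskPLSResults:
    """Non-rotated task-PLS for one a-priori contrast; exactly one LV."""
    return TaskPLS(data, PlsDesign("non_rotated", np.asarray(contrast))).fit(
        n_perm=n_perm, n_boot=n_boot, seed=seed, bsr_threshold=bsr_threshold)


def permutation_test(data: PlsDataMatrix, design: PlsDesign,
                     n_perm: int = 500, seed: int | None = None) -> np.ndarray:
    """Permutation p per LV under the restricted scheme."""
    return TaskPLS(data, design).fit(n_perm=n_perm, seed=seed).perm_p


def bootstrap_stability(data: PlsDataMatrix, design: PlsDesign,
                        n_boot: int = 500, seed: int | None = None,
                        threshold: float = DEFAULT_BSR_THRESHOLD,
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Bootstrap ratios and the |BSR| > threshold stability mask."""
    res = TaskPLS(data, design).fit(n_boot=n_boot, seed=seed,
                                    bsr_threshold=threshold)
    return res.bootstrap_ratios, res.stable_mask
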