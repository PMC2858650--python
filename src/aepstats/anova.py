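"""Balanced repeated-measures ANOVA with one optional between-subject
factor, Greenhouse-Geisser sphericity correction, partial eta squared,
simple-effect tests and Bonferroni pairwise comparisons.

The engine projects each subject's within-cell profile onto a full
orthonormal basis built from per-factor Helmert contrasts (scipy's
``helmert``), which splits the total sum of squares exactly into the
classical strata: the between-subjects stratum and, for every non-empty
subset S of within factors, the stratum spanned by S's contrasts with
error term S x Subject(Group).  Only fully crossed, balanced designs with
equal group sizes are accepted — no imputation, no sum-of-squares-type
ambiguity.

Greenhouse-Geisser epsilon for a stratum is computed from the pooled
within-group covariance of the orthonormal contrast scores,
eps = (sum lambda)^2 / (d * sum lambda^2) over its eigenvalues; the
GG-adjusted p rescales both degrees of freedom.  Epsilon is 1 by
construction when the stratum has a single contrast (numerator df 1).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import helmert
from scipy.stats import f as f_dist
from scipy.stats import t as t_dist

from .errors import ConfigError, DesignError, MissingDesignError

__all__ = ["RepeatedMeasuresAnova", "AnovaResults", "gg_epsilon"]


def gg_epsilon(contrast_cov: np.ndarray) -> tuple[float, bool]:
    """Greenhouse-Geisser epsilon from the covariance of orthonormalized
    contrast scores; returns (epsilon, degenerate_flag).

    For a k-level factor the covariance is (k-1) x (k-1) and epsilon lies
    in [1/(k-1), 1].  A zero (all-degenerate) covariance returns the lower
    bound with the flag set.
    """
    cov = np.atleast_2d(np.asarray(contrast_cov, dtype=float))
    d = cov.shape[0]
    lam = np.linalg.eigvalsh(cov)
    lam = np.clip(lam, 0.0, None)
    denom = d * float((lam ** 2).sum())
    if denom <= 0.0:
        return 1.0 / d, True
    return float(lam.sum() ** 2 / denom), False


@dataclass
class AnovaResults:
    """Fitted ANOVA: per-effect SS, uncorrected dfs, F, GG epsilon,
    uncorrected and GG-adjusted p, partial eta squared."""

    model: "RepeatedMeasuresAnova"
    anova_table: pd.DataFrame
    strata: dict = field(repr=False, default_factory=dict)

    def summary(self) -> str:
        t = self.anova_table
        lines = [f"Repeated-measures ANOVA, dv={self.model.dv!r}",
                 f"within: {self.model.within}"
                 + (f", between: {self.model.between}" if self.model.between else ""),
                 f"{'effect':<28}{'df':>9}{'F':>10}{'eps':>7}"
                 f"{'p(GG)':>10}{'pEta2':>8}"]
        for row in t.itertuples():
            lines.append(
                f"{row.effect:<28}{f'({row.df1:g},{row.df2:g})':>9}"
                f"{row.F:>10.3f}{row.eps:>7.3f}{row.p_gg:>10.4f}"
                f"{row.partial_eta_sq:>8.3f}")
        return "\n".join(lines)

    def effect(self, name: str) -> pd.Series:
        sel = self.anova_table[self.anova_table["effect"] == name]
        if sel.empty:
            raise KeyError(f"no effect {name!r} in the fitted table; "
                           f"have {list(self.anova_table['effect'])}")
        return sel.iloc[0]

    # -- post-hoc ---------------------------------------------------------
    def pairwise(self, factor: str, data: pd.DataFrame | None = None,
                 ) -> pd.DataFrame:
        """Bonferroni-adjusted pairwise paired comparisons between the
        levels of a within factor (collapsing over the other factors).
        A two-level factor yields its single comparison unadjusted."""
        m = self.model
        df = data if data is not None else m.data
        if factor not in m.within:
            raise DesignError(f"{factor!r} is not a within factor")
        cell = (df.groupby([m.subject, factor], sort=True)[m.dv]
                  .mean().unstack(factor))
        levels = list(cell.columns)
        pairs = list(itertools.combinations(levels, 2))
        n_comp = len(pairs) if len(pairs) > 1 else 1
        rows = []
        for a, b in pairs:
            diff = (cell[a] - cell[b]).to_numpy()
            n = len(diff)
            sd = diff.std(ddof=1)
            if sd == 0:
                tval, p = (0.0, 1.0) if np.allclose(diff, 0) else (np.inf, 0.0)
            else:
                tval = diff.mean() / (sd / np.sqrt(n))
                p = 2 * t_dist.sf(abs(tval), n - 1)
            rows.append(dict(factor=factor, level_a=a, level_b=b,
                             mean_diff=diff.mean(), t=tval, df=n - 1,
                             p_raw=p, p_bonferroni=min(1.0, p * n_comp),
                             n_comparisons=n_comp))
        return pd.DataFrame(rows)

    def simple_effects(self, factor: str, by: str) -> pd.DataFrame:
        """Simple main effects of ``factor`` within each level of ``by``,
        using the error term of the sliced data (per-level strata)."""
        m = self.model
        rows = []
        for level in sorted(m.data[by].unique()):
            sliced = m.data[m.data[by] == level]
            if by == m.between:
                sub = RepeatedMeasuresAnova(sliced, dv=m.dv, subject=m.subject,
                                            within=m.within, between=None)
            else:
                within = [w for w in m.within if w != by]
                if factor not in within and factor != m.between:
                    raise DesignError("factor collapsed out of the slice")
                sub = RepeatedMeasuresAnova(sliced, dv=m.dv, subject=m.subject,
                                            within=within, between=m.between)
            res = sub.fit()
            row = res.effect(factor).to_dict()
            row["slice"] = f"{by}={level}"
            rows.append(row)
        return pd.DataFrame(rows)


class RepeatedMeasuresAnova:
    """Model: a long-format table with one observation per subject x
    within-cell, an optional between-subject factor, and a numeric dv."""

    def __init__(self, data: pd.DataFrame, dv: str, subject: str,
                 within: list[str], between: str | None = None):
        if not within:
            raise ConfigError("need at least one within factor")
        self.data = data.reset_index(drop=True)
        self.dv = dv
        self.subject = subject
        self.within = list(within)
        self.between = between
        self._validate()

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, dv: str, subject: str,
                       within: list[str], between: str | None = None,
                       ) -> "RepeatedMeasuresAnova":
        return cls(data, dv=dv, subject=subject, within=within, between=between)

    # -- validation --------------------------------------------------------
    def _validate(self) -> None:
        cols = [self.subject, self.dv] + self.within
        if self.between:
            cols.append(self.between)
        missing = [c for c in cols if c not in self.data.columns]
        if missing:
            raise ConfigError(f"missing columns: {missing}")
        counts = self.data.groupby([self.subject] + self.within,
                                   sort=True).size()
        if (counts != 1).any():
            bad = counts[counts != 1].index[:3].tolist()
            raise MissingDesignError(
                f"design not balanced: cells with count != 1, e.g. {bad}")
        self.levels = {w: sorted(self.data[w].unique()) for w in self.within}
        n_cells = int(np.prod([len(self.levels[w]) for w in self.within]))
        per_subj = self.data.groupby(self.subject).size()
        if (per_subj != n_cells).any():
            raise MissingDesignError("subjects missing within-cells")
        if self.between:
            gmap = self.data.groupby(self.subject)[self.between].nunique()
            if (gmap != 1).any():
                raise DesignError("a subject appears in several groups")
            sizes = (self.data.groupby(self.between)[self.subject]
                     .nunique())
            if sizes.nunique() != 1:
                raise MissingDesignError(
                    f"unequal group sizes {dict(sizes)}; balanced-only engine")

    # -- fitting -----------------------------------------------------------
    def _tensor(self) -> tuple[np.ndarray, np.ndarray, list]:
        """subjects x cells matrix with cells ordered by the within-factor
        level product (last factor fastest), plus group codes."""
        level_lists = [self.levels[w] for w in self.within]
        cols = pd.MultiIndex.from_product(level_lists, names=self.within)
        piv = self.data.pivot_table(index=self.subject, columns=self.within,
                                    values=self.dv, aggfunc="first")
        if len(self.within) == 1:
            piv.columns = pd.MultiIndex.from_arrays([piv.columns],
                                                    names=self.within)
        piv = piv.reindex(columns=cols)
        if piv.isna().any().any():
            raise MissingDesignError("missing within-cells after pivot")
        subjects = list(piv.index)
        if self.between:
            gser = self.data.groupby(self.subject)[self.between].first()
            groups = np.array([gser[s] for s in subjects])
        else:
            groups = np.zeros(len(subjects))
        return piv.to_numpy(float), groups, subjects

    def _bases(self) -> dict[tuple[str, ...], np.ndarray]:
        """Orthonormal basis rows for every within-factor subset."""
        mats = {}
        for w in self.within:
            k = len(self.levels[w])
            if k < 2:
                raise ConfigError(f"factor {w!r} needs >= 2 levels")
            mats[w] = helmert(k, full=False)          # (k-1, k) orthonormal
        units = {w: np.full((1, len(self.levels[w])),
                            1.0 / np.sqrt(len(self.levels[w])))
                 for w in self.within}
        bases = {}
        subsets = []
        for r in range(1, len(self.within) + 1):
            subsets.extend(itertools.combinations(self.within, r))
        for S in subsets:
            B = np.ones((1, 1))
            for w in self.within:
                B = np.kron(B, mats[w] if w in S else units[w])
            bases[S] = B
        return bases

    def fit(self) -> AnovaResults:
        Y, groups, _subjects = self._tensor()
        n_subj = Y.shape[0]
        glevels = sorted(pd.unique(groups))
        G = len(glevels)
        gidx = [np.flatnonzero(groups == g) for g in glevels]
        g_of_subj = np.array([glevels.index(g) for g in groups])
        rows, strata = [], {}

        def add_row(effect, ss, df1, ss_err, df2, eps, apply_gg):
            if ss_err <= 0.0:
                F = 0.0 if ss <= 1e-24 else np.inf
            else:
                F = (ss / df1) / (ss_err / df2)
            p_unc = float(f_dist.sf(F, df1, df2)) if np.isfinite(F) else 0.0
            if F == 0.0 and ss_err <= 0.0:
                p_unc = 1.0
            if apply_gg and np.isfinite(F):
                p_gg = float(f_dist.sf(F, eps * df1, eps * df2))
            else:
                p_gg = p_unc
            eta = ss / (ss + ss_err) if (ss + ss_err) > 0 else 0.0
            rows.append(dict(effect=effect, SS=ss, df1=df1, df2=df2, F=F,
                             eps=eps, p_unc=p_unc, p_gg=p_gg,
                             partial_eta_sq=eta))

        # between-subjects stratum
        z0 = Y.mean(axis=1) * np.sqrt(Y.shape[1])   # orthonormal constant
        gm = z0.mean()
        ss_err_b = sum(((z0[idx] - z0[idx].mean()) ** 2).sum() for idx in gidx)
        df_err_b = n_subj - G
        if self.between:
            ss_b = sum(len(idx) * (z0[idx].mean() - gm) ** 2 for idx in gidx)
            add_row(self.between, ss_b, G - 1, ss_err_b, df_err_b, 1.0, False)
        strata["between"] = dict(ss_err=ss_err_b, df_err=df_err_b)

        # within strata
        for S, B in self._bases().items():
            Z = Y @ B.T                                  # n_subj x d
            d = Z.shape[1]
            zbar = Z.mean(axis=0)
            ss_S = n_subj * float(zbar @ zbar)
            gmeans = np.stack([Z[idx].mean(axis=0) for idx in gidx])
            Zc = Z - gmeans[g_of_subj]
            ss_err = float((Zc ** 2).sum())
            df_err = (n_subj - G) * d
            cov = Zc.T @ Zc / max(n_subj - G, 1)
            eps, _degen = gg_epsilon(cov)
            name = ":".join(S)
            add_row(name, ss_S, d, ss_err, df_err, eps, d > 1)
            if self.between:
                ss_int = float(sum(len(idx) * ((gmeans[i] - zbar) ** 2).sum()
                                   for i, idx in enumerate(gidx)))
                add_row(f"{self.between}:{name}", ss_int, (G - 1) * d,
                        ss_err, df_err, eps, d > 1)
            strata[S] = dict(ss_err=ss_err, df_err=df_err, eps=eps)

        table = pd.DataFrame(rows)
        return AnovaResults(model=self, anova_table=table, strata=strata)
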