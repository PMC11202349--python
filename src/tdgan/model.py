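"""Model/Results front for the two-stage imputer.

:class:`UganGrudModel` is constructed from a dataset of sparse records and
fitted like a statsmodels model: ``fit()`` runs normalization, the
adversarial stage, the decay-correction stage, and de-normalization, and
returns a :class:`UganGrudResults` carrying the dense imputed matrices, the
uncertainty streams, training diagnostics and a ``summary()`` table.  The
stage switches (``use_uncertainty``, ``use_grud``) expose the ablation
variants: Base (neither), Base+UGAN (uncertainty only), Base+GRUD (corrector
on a zero uncertainty stream), and the full model.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .data_model import MaskedSeries, NormalizationState, build_mask
from .grud import GrudConfig, GrudParams, impute as grud_impute, train_grud
from .metrics import EvalReport, evaluate_heldout
from .ugan import ImputationResult, UganConfig, train_ugan

__all__ = ["UganGrudModel", "UganGrudResults", "normalize_dataset"]


def normalize_dataset(records: list, lo: float = -1.0, hi: float = 1.0,
                      ) -> tuple[list, NormalizationState]:
    """Per-feature min-max normalization pooled across all records.

    Features are shared across records, so one affine map per feature is
    fitted on the union of observed values and applied everywhere; missing
    cells keep the placeholder 0.
    """
    d = records[0].n_features
    vmin = np.full(d, np.inf)
    vmax = np.full(d, -np.inf)
    for rec in records:
        obs = rec.mask == 1.0
        for j in range(d):
            if obs[j].any():
                vmin[j] = min(vmin[j], rec.values[j, obs[j]].min())
                vmax[j] = max(vmax[j], rec.values[j, obs[j]].max())
    never = ~np.isfinite(vmin)
    vmin[never] = 0.0
    vmax[never] = 0.0
    state = NormalizationState(vmin, vmax, lo, hi)
    normalized = [
        MaskedSeries(state.forward(r.values) * r.mask, r.mask.copy(),
                     r.times.copy(), list(r.feature_names))
        for r in records
    ]
    return normalized, state


@dataclass
class UganGrudResults:
    """Fitted two-stage imputation results.

    ``imputed`` holds one dense ``d x n`` matrix per record on the original
    measurement scale, with observed cells passed through exactly.
    """

    model: "UganGrudModel"
    imputed: list
    stage1: list
    ugan_state: object
    grud_params: GrudParams | None
    grud_history: list | None
    norm_state: NormalizationState

    @property
    def uncertainty(self) -> list:
        """Per-record, per-timestep uncertainty streams (normalized scale)."""
        return [s.uncertainty for s in self.stage1]

    def evaluate(self, heldout, **kwargs) -> EvalReport:
        """Held-out RMSE/MAPE of the imputed matrices, original scale."""
        return evaluate_heldout(heldout, self.imputed, **kwargs)

    def summary(self) -> str:
        m = self.model
        rows = [
            ("records", len(m.records)),
            ("features", m.records[0].n_features),
            ("total cells", sum(r.mask.size for r in m.records)),
            ("observed fraction",
             f"{np.mean([r.mask.mean() for r in m.records]):.3f}"),
            ("adversarial iterations", m.ugan_config.n_iter),
            ("final D loss", f"{self.ugan_state.d_loss_history[-1]:.4f}"),
            ("final G loss", f"{self.ugan_state.g_loss_history[-1]:.4f}"),
            ("final observed-cell recon MSE",
             f"{self.ugan_state.recon_history[-1]:.5f}"),
            ("mean uncertainty",
             f"{np.mean(np.concatenate(self.uncertainty)):.4f}"),
        ]
        if self.grud_history is not None:
            rows += [
                ("corrector epochs", m.grud_config.epochs),
                ("corrector hidden size", m.grud_config.hidden_size),
                ("final corrector MAE", f"{self.grud_history[-1]:.5f}"),
            ]
        variant = m.variant_name
        width = max(len(k) for k, _ in rows)
        lines = ["Two-stage time-series imputation results",
                 "=" * 44,
                 f"variant: {variant}"]
        lines += [f"{k.ljust(width)} : {v}" for k, v in rows]
        return "\n".join(lines)


class UganGrudModel:
    """Two-stage imputer over a dataset of sparse multivariate records.

    Parameters
    ----------
    records : list of MaskedSeries
        The sparse records to impute, on their original scale.
    ugan_config, grud_config : optional
        Stage hyperparameters; defaults follow the package conventions
        (batch 128, learning rate 0.001, Adam).
    use_uncertainty : bool
        When False the uncertainty stream is forced to zero (the "Base"
        adversarial imputer of the ablation design).
    use_grud : bool
        When False the stage-1 merged fill is the final output.
    """

    def __init__(self, records: list, ugan_config: UganConfig | None = None,
                 grud_config: GrudConfig | None = None,
                 use_uncertainty: bool = True, use_grud: bool = True):
        if not records:
            raise ValueError("need at least one record")
        self.records = records
        self.ugan_config = ugan_config or UganConfig()
        self.grud_config = grud_config or GrudConfig()
        self.use_uncertainty = use_uncertainty
        self.use_grud = use_grud

    @classmethod
    def from_dataframe(cls, df, time_column: str = "time", **kwargs):
        """Build from a single wide table (one record)."""
        return cls([build_mask(df, time_column=time_column)], **kwargs)

    @property
    def variant_name(self) -> str:
        return {(False, False): "base",
                (False, True): "base+grud",
                (True, False): "base+ugan",
                (True, True): "full"}[(self.use_uncertainty, self.use_grud)]

    def fit(self, seed: int | None = None, fit_records: list | None = None,
            ) -> UganGrudResults:
        """Train both stages and impute every record.

        ``seed`` overrides the config seeds (one seed drives both stages).
        ``fit_records`` optionally restricts training to a subset (e.g. a
        train split) while imputation still covers every record of the
        model.
        """
        ucfg = self.ugan_config
        gcfg = self.grud_config
        if seed is not None:
            ucfg = replace(ucfg, seed=seed)
            gcfg = replace(gcfg, seed=seed)
        norm_records, state = normalize_dataset(self.records)
        if fit_records is None:
            train_set = norm_records
        else:
            train_set = [
                MaskedSeries(state.forward(r.values) * r.mask, r.mask.copy(),
                             r.times.copy(), list(r.feature_names))
                for r in fit_records
            ]

        ugan_state, _ = train_ugan(train_set, ucfg)
        from .ugan import apply_ugan
        rng = np.random.default_rng(ucfg.seed + 1)
        stage1 = [apply_ugan(ugan_state, r, rng) for r in norm_records]
        if not self.use_uncertainty:
            stage1 = [ImputationResult(s.ddm, s.merged,
                                       np.zeros_like(s.uncertainty))
                      for s in stage1]

        grud_params = grud_history = None
        if self.use_grud:
            if fit_records is None:
                grud_train, grud_train_s1 = norm_records, stage1
            else:
                grud_train = train_set
                grud_train_s1 = [apply_ugan(ugan_state, r,
                                            np.random.default_rng(ucfg.seed + 2))
                                 for r in train_set]
                if not self.use_uncertainty:
                    grud_train_s1 = [
                        ImputationResult(s.ddm, s.merged,
                                         np.zeros_like(s.uncertainty))
                        for s in grud_train_s1]
            grud_params, grud_history = train_grud(grud_train, grud_train_s1,
                                                   gcfg)

        imputed = []
        for rec, norm_rec, s1 in zip(self.records, norm_records, stage1):
            if self.use_grud:
                dense = grud_impute(norm_rec, s1, grud_params, gcfg,
                                    norm_state=None)
            else:
                dense = s1.merged
            dense = state.inverse(dense)
            obs = rec.mask == 1.0
            dense[obs] = rec.values[obs]   # observed cells exactly preserved
            imputed.append(dense)
        return UganGrudResults(model=self, imputed=imputed, stage1=stage1,
                               ugan_state=ugan_state,
                               grud_params=grud_params,
                               grud_history=grud_history, norm_state=state)
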