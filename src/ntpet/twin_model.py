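"""Normal-twin PET predictors.

Three interchangeable estimators predict a patient-specific *normal* PET
volume from CT-derived anatomy and study attributes — never from the PET
itself, so anomalies in the observed PET cannot leak into the prediction:

``ConstantOrganMapPredictor``
    The reference method: organ masks filled with cohort-average per-organ
    SUVmean values.
``OrganRegressionPredictor``
    Per-organ ordinary least squares of organ SUVmean on the study
    covariates (sex, age, fat body mass, uptake time, seasonal sin-cos);
    organs are filled with the fitted mean for the study's attributes.
``ConvTranslatorPredictor``
    A scaled-down patch-based convolutional CT-to-PET translator trained
    with a masked L1 loss, with optional attribute conditioning at the
    deepest layer and optional organ-label input channels.  Full volumes are
    assembled from overlapping axial patches blended with generalized-normal
    weights.

All predictors follow the scikit-learn estimator protocol (``fit`` /
``predict`` / ``get_params`` / ``set_params``) and compose with sklearn
tooling; fitted state carries a trailing underscore.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator

from . import nn
from .grid import Grid3D, GridError
from .labels import BACKGROUND, DEFAULT_LABELS
from .phantom import EffectModel, Study, StudyAttributes, render_normal_pet
from .preprocess import PreprocessConfig, clamp_rescale_ct

__all__ = [
    "AttributeCodebook",
    "AttributeEncoding",
    "PatchSpec",
    "TrainConfig",
    "encode_attributes",
    "cyclic_pair",
    "axial_stride",
    "axial_offsets",
    "blend_weights",
    "assemble_volume",
    "masked_l1",
    "evaluate_prediction",
    "ConstantOrganMapPredictor",
    "OrganRegressionPredictor",
    "ConvTranslatorPredictor",
    "OracleTwinPredictor",
    "design_matrix",
    "REGRESSION_COLUMNS",
]


# ---------------------------------------------------------------------------
# attribute encoding


def cyclic_pair(value: float, period: float) -> tuple[float, float]:
    """(sin, cos) encoding of a periodic quantity; continuous across wrap."""
    angle = 2.0 * np.pi * value / period
    return float(np.sin(angle)), float(np.cos(angle))


@dataclass
class AttributeEncoding:
    vector: np.ndarray  # length-16 context vector
    raw: np.ndarray     # pre-projection features

    def __post_init__(self) -> None:
        if self.vector.shape != (16,):
            raise GridError("context vector must have length 16")


@dataclass
class AttributeCodebook:
    """Deterministic attribute encoder.

    Continuous attributes are standardised, time attributes get sin-cos
    pairs, and each categorical gets a fixed 3-d embedding (seeded), with a
    reserved 'unknown' row for unseen categories.  The raw feature vector is
    projected to length 16 by a fixed 3-layer feed-forward map.
    """

    scanner_models: tuple[str, ...] = ("vision_quadra", "vision_600", "mct_flow", "truepoint")
    standardize: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "age": (60.5, 17.3),
            "weight": (77.0, 14.0),
            "injected_activity": (256.0, 66.0),
            "uptake_time": (63.0, 6.0),
        }
    )
    seed: int = 7

    _EMB_DIM = 3
    _RAW_DIM = 4 + 4 + 2 * _EMB_DIM  # sincos day + sincos tod + 4 continuous + 2 embeddings

    def __post_init__(self) -> None:
        rng = np.random.default_rng(self.seed)
        self._sex_emb = {
            s: rng.standard_normal(self._EMB_DIM) for s in ("M", "F", "__unknown__")
        }
        self._scanner_emb = {
            m: rng.standard_normal(self._EMB_DIM)
            for m in (*self.scanner_models, "__unknown__")
        }
        d1, d2 = 24, 24
        self._W1 = rng.standard_normal((d1, self._RAW_DIM)) / np.sqrt(self._RAW_DIM)
        self._b1 = rng.standard_normal(d1) * 0.1
        self._W2 = rng.standard_normal((d2, d1)) / np.sqrt(d1)
        self._b2 = rng.standard_normal(d2) * 0.1
        self._W3 = rng.standard_normal((16, d2)) / np.sqrt(d2)

    @classmethod
    def fit(cls, attributes: list[StudyAttributes], seed: int = 7) -> "AttributeCodebook":
        """Codebook with standardisation statistics taken from a cohort."""
        stats = {}
        for name in ("age", "weight", "injected_activity", "uptake_time"):
            vals = np.array([getattr(a, name) for a in attributes], dtype=float)
            stats[name] = (float(vals.mean()), float(vals.std() or 1.0))
        models = tuple(sorted({a.scanner_model for a in attributes}))
        return cls(scanner_models=models, standardize=stats, seed=seed)

    def _embed(self, table: dict[str, np.ndarray], key: str, what: str) -> np.ndarray:
        if key not in table:
            warnings.warn(f"unseen {what} category {key!r}; using reserved embedding",
                          stacklevel=3)
            return table["__unknown__"]
        return table[key]

    def raw_features(self, a: StudyAttributes) -> np.ndarray:
        day_sc = cyclic_pair(a.scan_day_of_year, 365.0)
        tod_sc = cyclic_pair(a.scan_time_of_day, 24.0)
        cont = [
            (getattr(a, name) - mu) / sd
            for name, (mu, sd) in self.standardize.items()
        ]
        sex = self._embed(self._sex_emb, a.sex, "sex")
        scanner = self._embed(self._scanner_emb, a.scanner_model, "scanner_model")
        return np.concatenate([day_sc, tod_sc, cont, sex, scanner])

    def encode(self, a: StudyAttributes) -> AttributeEncoding:
        raw = self.raw_features(a)
        h = np.tanh(self._W1 @ raw + self._b1)
        h = np.tanh(self._W2 @ h + self._b2)
        return AttributeEncoding(vector=self._W3 @ h, raw=raw)


def encode_attributes(attributes: StudyAttributes,
                      codebook: AttributeCodebook) -> AttributeEncoding:
    """Encode one attribute record to a length-16 context vector."""
    return codebook.encode(attributes)


# ---------------------------------------------------------------------------
# patch geometry and blending


@dataclass
class PatchSpec:
    """Axial patching: full transaxial extent x ``depth`` slices.

    ``overlap`` is the axial overlap fraction between consecutive patches;
    blending uses a generalized normal profile exp(-(|z-c|/alpha)^beta) with
    ``alpha`` defaulting to 0.4 x depth.  Clinical reference depth is 32; the
    phantom-scale default is 8.
    """

    depth: int = 8
    overlap: float = 0.666
    beta: float = 4.0
    alpha: float | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.overlap < 1:
            raise GridError("overlap must lie in [0, 1)")
        if self.beta < 2:
            raise GridError("beta must be >= 2")
        if self.depth < 1:
            raise GridError("depth must be >= 1")

    @property
    def alpha_value(self) -> float:
        return self.alpha if self.alpha is not None else 0.4 * self.depth


def axial_stride(patch_depth: int, overlap: float) -> int:
    """Stride between patch starts: depth x (1 - overlap), rounded
    half-away-from-zero, never below 1."""
    if not 0 <= overlap < 1:
        raise GridError("overlap must lie in [0, 1)")
    raw = patch_depth * (1.0 - overlap)
    return max(1, int(np.floor(raw + 0.5)))


def axial_offsets(n_slices: int, depth: int, stride: int) -> list[int]:
    """Patch start offsets covering [0, n_slices); the last patch is clamped
    flush with the end."""
    if depth > n_slices:
        raise GridError(f"patch depth {depth} exceeds axial extent {n_slices}")
    offsets = list(range(0, n_slices - depth + 1, stride))
    if offsets[-1] != n_slices - depth:
        offsets.append(n_slices - depth)
    return offsets


def blend_weights(patch_depth: int, beta: float, alpha: float) -> np.ndarray:
    """Per-slice generalized-normal weights, maximal (1.0) at the patch
    centre, symmetric and strictly positive."""
    if beta < 2 or alpha <= 0:
        raise GridError("need beta >= 2 and alpha > 0")
    z = np.arange(patch_depth, dtype=np.float64)
    c = (patch_depth - 1) / 2.0
    return np.exp(-np.power(np.abs(z - c) / alpha, beta))


def assemble_volume(
    patch_predictions: list[tuple[int, np.ndarray]],
    weights: np.ndarray,
    output_shape: tuple[int, int, int],
) -> np.ndarray:
    """Weight-normalised average of overlapping axial patches.

    Every axial slice must be covered by at least one patch; per-voxel
    weights are renormalised to sum to one.
    """
    acc = np.zeros(output_shape, dtype=np.float64)
    wacc = np.zeros(output_shape[2], dtype=np.float64)
    for z0, patch in patch_predictions:
        d = patch.shape[2]
        if patch.shape[:2] != output_shape[:2] or z0 < 0 or z0 + d > output_shape[2]:
            raise GridError("patch does not fit the output volume")
        w = weights[:d]
        acc[:, :, z0:z0 + d] += patch * w[None, None, :]
        wacc[z0:z0 + d] += w
    if np.any(wacc <= 0):
        uncovered = np.where(wacc <= 0)[0]
        raise GridError(f"axial slices not covered by any patch: {uncovered[:10]}")
    return acc / wacc[None, None, :]


# ---------------------------------------------------------------------------
# losses and metrics


def masked_l1(pred: Grid3D, target: Grid3D, body_mask: Grid3D,
              exclusion_mask: Grid3D | None = None) -> float:
    """Mean |pred - target| inside the body and outside the exclusion mask."""
    pred.assert_congruent(target, "pred/target")
    pred.assert_congruent(body_mask, "pred/body_mask")
    mask = body_mask.data.astype(bool)
    if exclusion_mask is not None:
        pred.assert_congruent(exclusion_mask, "pred/exclusion_mask")
        mask &= ~exclusion_mask.data.astype(bool)
    if not mask.any():
        raise GridError("empty effective loss mask")
    return float(np.abs(pred.data[mask] - target.data[mask]).mean())


def evaluate_prediction(pet: Grid3D, ntpet: Grid3D, body_mask: Grid3D,
                        eps: float = 0.1) -> dict[str, float]:
    """Whole-body agreement between observed PET and its normal twin.

    Returns explained variance (percent), SUV MAE, and mean absolute
    relative error (percent, with the denominator floored at ``eps`` SUV).
    """
    pet.assert_congruent(ntpet, "pet/ntpet")
    pet.assert_congruent(body_mask, "pet/body_mask")
    m = body_mask.data.astype(bool)
    if not m.any():
        raise GridError("empty body mask")
    p = pet.data[m].astype(np.float64)
    t = ntpet.data[m].astype(np.float64)
    var_p = p.var()
    if var_p == 0:
        raise GridError("zero PET variance: explained variance undefined")
    diff = p - t
    return {
        "explained_variance": float(100.0 * (1.0 - diff.var() / var_p)),
        "suv_mae": float(np.abs(diff).mean()),
        "mare": float(100.0 * np.mean(np.abs(diff) / np.maximum(p, eps))),
    }


# ---------------------------------------------------------------------------
# predictors


def _study_organ_means(study: Study, label_map: dict[str, int]) -> dict[str, float]:
    from .twin_correction import organ_suv_mean

    labels = study.organ_labels
    out = {}
    for organ, lab in label_map.items():
        if np.any(labels.data == lab):
            out[organ] = organ_suv_mean(study.pet, labels, lab)
    return out


def _fill_organs(study: Study, values: dict[str, float],
                 label_map: dict[str, int]) -> Grid3D:
    labels = study.organ_labels.data
    n = int(labels.max()) + 1
    table = np.zeros(n, dtype=np.float64)
    for organ, v in values.items():
        lab = label_map.get(organ)
        if lab is not None and lab < n:
            table[lab] = max(v, 0.0)
    return study.organ_labels.like(table[labels])


class ConstantOrganMapPredictor(BaseEstimator):
    """Reference twin: organ masks filled with training-cohort mean SUVs.

    Per organ, the per-study SUVmean values of the training studies are
    averaged (unweighted mean of means) and test organs are filled with
    those constants.
    """

    def __init__(self, label_map: dict[str, int] | None = None):
        self.label_map = label_map

    def fit(self, studies: list[Study], y=None) -> "ConstantOrganMapPredictor":
        label_map = self.label_map or DEFAULT_LABELS
        per_organ: dict[str, list[float]] = {}
        for study in studies:
            for organ, mean in _study_organ_means(study, label_map).items():
                per_organ.setdefault(organ, []).append(mean)
        absent = set(label_map) - set(per_organ) - {"background"}
        if absent:
            warnings.warn(f"organs absent from every training study: {sorted(absent)}")
        self.organ_map_ = {o: float(np.mean(v)) for o, v in per_organ.items()}
        self.n_studies_ = len(studies)
        return self

    def predict(self, study: Study) -> Grid3D:
        return _fill_organs(study, self.organ_map_, self.label_map or DEFAULT_LABELS)


REGRESSION_COLUMNS = (
    "intercept", "sex_f", "age_c", "fat_body_mass", "uptake_time_c",
    "season_sin", "season_cos",
)


def design_matrix(attributes: list[StudyAttributes],
                  age_ref: float = 60.0, uptake_ref: float = 63.0) -> np.ndarray:
    """Covariate design for the organ regression (columns
    :data:`REGRESSION_COLUMNS`)."""
    from .phantom import fat_body_mass

    rows = []
    for a in attributes:
        s, c = cyclic_pair(a.scan_day_of_year, 365.0)
        rows.append([
            1.0,
            1.0 if a.sex == "F" else 0.0,
            a.age - age_ref,
            fat_body_mass(a),
            a.uptake_time - uptake_ref,
            s,
            c,
        ])
    return np.asarray(rows, dtype=np.float64)


class OrganRegressionPredictor(BaseEstimator):
    """Attribute-conditioned twin: per-organ OLS on study covariates.

    A desk-scale stand-in for the convolutional model that captures exactly
    the global covariate effects a local patch cannot see.  Prediction fills
    each organ with its fitted mean for the study's attributes, clamped at 0.
    """

    def __init__(self, label_map: dict[str, int] | None = None,
                 age_ref: float = 60.0, uptake_ref: float = 63.0):
        self.label_map = label_map
        self.age_ref = age_ref
        self.uptake_ref = uptake_ref

    def fit(self, studies: list[Study], y=None) -> "OrganRegressionPredictor":
        if len(studies) < 10:
            raise GridError(f"organ regression needs >= 10 studies, got {len(studies)}")
        label_map = self.label_map or DEFAULT_LABELS
        X = design_matrix([s.attributes for s in studies],
                          self.age_ref, self.uptake_ref)
        if np.linalg.matrix_rank(X) < X.shape[1]:
            warnings.warn("rank-deficient covariate design; "
                          "coefficients are the minimum-norm solution")
        organ_means: dict[str, list[float]] = {}
        for study in studies:
            for organ, mean in _study_organ_means(study, label_map).items():
                organ_means.setdefault(organ, []).append(mean)
        self.coef_: dict[str, np.ndarray] = {}
        for organ, values in organ_means.items():
            if len(values) != len(studies):
                # organ missing from some studies: fall back to its plain mean
                self.coef_[organ] = np.r_[np.mean(values), np.zeros(X.shape[1] - 1)]
                continue
            beta, *_ = np.linalg.lstsq(X, np.asarray(values), rcond=None)
            self.coef_[organ] = beta
        self.n_studies_ = len(studies)
        return self

    def predict_organ_means(self, attributes: StudyAttributes) -> dict[str, float]:
        x = design_matrix([attributes], self.age_ref, self.uptake_ref)[0]
        return {organ: float(x @ beta) for organ, beta in self.coef_.items()}

    def predict(self, study: Study) -> Grid3D:
        return _fill_organs(study, self.predict_organ_means(study.attributes),
                            self.label_map or DEFAULT_LABELS)


class OracleTwinPredictor(BaseEstimator):
    """Ground-truth twin: noise-free re-render of the phantom's normal PET.

    Only meaningful on synthetic studies whose generating
    :class:`~ntpet.phantom.EffectModel` is known; serves as the ideal
    predictor when validating the correction and anomaly stages.
    """

    def __init__(self, effect_model: EffectModel | None = None):
        self.effect_model = effect_model

    def fit(self, studies: list[Study] | None = None, y=None) -> "OracleTwinPredictor":
        if self.effect_model is None:
            raise GridError("OracleTwinPredictor requires the generating effect model")
        self.effect_model_ = self.effect_model
        return self

    def predict(self, study: Study) -> Grid3D:
        import dataclasses

        em = dataclasses.replace(self.effect_model_, voxel_noise_sd=0.0)
        return render_normal_pet(study.organ_labels, study.attributes, em, seed=0)


@dataclass
class TrainConfig:
    """Conv-translator optimisation settings.

    The clinical reference schedule is 80,000 steps at lr 1e-4 decayed to
    1e-5 at 62.5% of training, batch size 2, masked L1 loss; the scaled-down
    default keeps the shape of that schedule at 2,000 steps.
    """

    steps: int = 2000
    lr: float = 1e-4
    lr_final: float = 1e-5
    decay_frac: float = 0.625
    batch_size: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.steps <= 0:
            raise GridError("steps must be positive")
        if not 0 < self.decay_frac < 1:
            raise GridError("decay_frac must lie in (0, 1)")

    @property
    def decay_step(self) -> int:
        return int(round(self.decay_frac * self.steps))

    def lr_at(self, step: int) -> float:
        return self.lr if step < self.decay_step else self.lr_final


class ConvTranslatorPredictor(BaseEstimator):
    """Patch-based convolutional CT-to-PET translator (scaled down).

    Trains on randomly sampled axial patches (full transaxial extent x
    ``patch_spec.depth`` slices) with a masked L1 loss that ignores voxels
    outside the body or inside disease exclusion masks.  Optional inputs:
    the 16-d attribute encoding injected as a bias at the deepest
    convolution, and a fixed 4-d embedding of the organ label map as extra
    input channels.
    """

    _LABEL_EMB_DIM = 4

    def __init__(
        self,
        patch_spec: PatchSpec | None = None,
        train_config: TrainConfig | None = None,
        channels: int = 12,
        use_attributes: bool = False,
        use_labels: bool = False,
        use_exclusion_masks: bool = True,
        smooth_sigma_vox: float = 2.0,
        preprocess_config: PreprocessConfig | None = None,
        codebook: AttributeCodebook | None = None,
    ):
        self.patch_spec = patch_spec
        self.train_config = train_config
        self.channels = channels
        self.use_attributes = use_attributes
        self.use_labels = use_labels
        self.use_exclusion_masks = use_exclusion_masks
        self.smooth_sigma_vox = smooth_sigma_vox
        self.preprocess_config = preprocess_config
        self.codebook = codebook

    # -- input assembly ----------------------------------------------------

    def _label_embedding(self, n_labels: int, seed: int) -> np.ndarray:
        rng = np.random.default_rng(seed + 101)
        emb = rng.standard_normal((n_labels, self._LABEL_EMB_DIM)) * 0.5
        emb[BACKGROUND] = 0.0
        return emb

    def _inputs(self, study: Study) -> np.ndarray:
        from scipy import ndimage

        cfg = self.preprocess_config or PreprocessConfig()
        # centred so soft tissue sits near 0 (keeps ReLU units alive on
        # all-positive CT); a smoothed copy gives a cheap second scale so
        # tissues separable only by neighbourhood mean need no learned
        # averaging filters
        ct = clamp_rescale_ct(study.ct, cfg).data - 1.0
        chans = [ct]
        if self.smooth_sigma_vox > 0:
            chans.append(ndimage.gaussian_filter(ct, self.smooth_sigma_vox))
        if self.use_labels:
            emb = self.label_embedding_
            labels = np.clip(study.organ_labels.data, 0, emb.shape[0] - 1)
            chans.extend(emb[labels, i] for i in range(self._LABEL_EMB_DIM))
        return np.stack(chans).astype(np.float64)

    def _context(self, study: Study) -> np.ndarray | None:
        if not self.use_attributes:
            return None
        return self.codebook_.encode(study.attributes).vector

    # -- training ----------------------------------------------------------

    def fit(self, studies: list[Study], y=None) -> "ConvTranslatorPredictor":
        spec = self.patch_spec or PatchSpec()
        cfg = self.train_config or TrainConfig()
        rng = np.random.default_rng(cfg.seed)

        self.codebook_ = self.codebook or AttributeCodebook.fit(
            [s.attributes for s in studies]
        )
        max_label = max(int(s.organ_labels.data.max()) for s in studies)
        self.label_embedding_ = self._label_embedding(max_label + 1, cfg.seed)

        inputs = [self._inputs(s) for s in studies]
        targets = [s.pet.data.astype(np.float64) for s in studies]
        contexts = [self._context(s) for s in studies]
        masks = []
        for s in studies:
            m = s.body_mask.data.astype(bool)
            if self.use_exclusion_masks and s.exclusion_mask is not None:
                m = m & ~s.exclusion_mask.data.astype(bool)
            masks.append(m)

        c_in = inputs[0].shape[0]
        ctx_dim = 16 if self.use_attributes else 0
        self.net_ = nn.ConvNet(c_in, self.channels, ctx_dim, seed=cfg.seed)
        opt = nn.Adam(self.net_.params, lr=cfg.lr)
        nz = inputs[0].shape[3]
        depth = min(spec.depth, nz)

        self.loss_history_ = []
        for step in range(cfg.steps):
            opt.lr = cfg.lr_at(step)
            grads_acc = None
            loss_acc = 0.0
            for _ in range(cfg.batch_size):
                i = int(rng.integers(len(studies)))
                z0 = int(rng.integers(inputs[i].shape[3] - depth + 1))
                x = inputs[i][:, :, :, z0:z0 + depth]
                t = targets[i][:, :, z0:z0 + depth]
                m = masks[i][:, :, z0:z0 + depth]
                if not m.any():
                    continue
                pred = self.net_.forward(x, contexts[i], train=True)[0]
                loss, dpred = nn.masked_l1_and_grad(pred, t, m)
                grads = self.net_.backward(dpred[None])
                loss_acc += loss
                if grads_acc is None:
                    grads_acc = grads
                else:
                    grads_acc = [a + g for a, g in zip(grads_acc, grads)]
            if grads_acc is None:
                continue
            if not np.isfinite(loss_acc):
                raise RuntimeError(
                    f"training diverged at step {step}: loss={loss_acc}"
                )
            opt.step([g / cfg.batch_size for g in grads_acc])
            self.loss_history_.append(loss_acc / cfg.batch_size)
        self.patch_spec_ = PatchSpec(depth, spec.overlap, spec.beta, spec.alpha)
        return self

    # -- inference ---------------------------------------------------------

    def predict(self, study: Study) -> Grid3D:
        spec = self.patch_spec_
        x = self._inputs(study)
        ctx = self._context(study)
        nz = x.shape[3]
        depth = min(spec.depth, nz)
        stride = axial_stride(depth, spec.overlap)
        weights = blend_weights(depth, spec.beta, spec.alpha_value)
        patches = []
        for z0 in axial_offsets(nz, depth, stride):
            pred = self.net_.forward(x[:, :, :, z0:z0 + depth], ctx, train=False)[0]
            patches.append((z0, pred))
        vol = assemble_volume(patches, weights, study.ct.shape)
        return study.ct.like(np.maximum(vol, 0.0))
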