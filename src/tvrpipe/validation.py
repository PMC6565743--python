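"""End-to-end recovery checks run on synthetic sessions.

Each function regenerates its inputs from a seed, runs the relevant pipeline
stages, and returns the measured quantities.  These are the checks behind
the package's validation suite and the reproduction script: analytic
rate-conversion bounds, onset-detector oracle agreement, mutual-information
estimator sanity, and parameter-recovery for categories, speed tuning, the
encoding model, the calcium forward model, touch-response suppression, and
the sound-control false-positive rate.
"""

from __future__ import annotations

import numpy as np

from .classification import bootstrap_condition_means, classify
from .config import PipelineConfig
from .encoding import all_shuffle_importances, fit_encoding_model
from .info import BinningSpec, mutual_information
from .pipeline import preprocess_stage
from .preprocess import rate_from_steady_state
from .response import align_and_average, touch_metrics
from .segmentation import detect_onsets, segment_session, touch_onsets
from .synth import BehaviorConfig, NeuronSpec, generate_behavior, generate_fluorescence
from .tuning import equal_occupancy_bins, fit_speed_tuning


def _sub_seed(seed: int, k: int) -> int:
    return (seed * 1000 + k) % (2**31 - 1)


# -- 1: analytic rate conversion -------------------------------------------

def rate_conversion_bounds(dff_ss: float = 0.5) -> dict:
    """Rounded firing-rate bounds for a 50% steady-state dF/F over the
    single-AP kernel ranges A in [8, 11]% and tau in [0.3, 0.4] s."""
    rates = [
        rate_from_steady_state(dff_ss, a, t)
        for a in np.linspace(0.08, 0.11, 7)
        for t in np.linspace(0.3, 0.4, 7)
    ]
    return {"min_hz": round(min(rates)), "max_hz": round(max(rates)), "n": len(rates)}


# -- 2: onset detector vs exhaustive scan ----------------------------------

def onset_oracle_agreement(seed: int = 0, n_sequences: int = 1000) -> dict:
    rng = np.random.default_rng(seed)
    agree = 0
    for _ in range(n_sequences):
        b = (rng.uniform(size=60) < rng.uniform(0.2, 0.8)).astype(int)
        ours = [int(round(t * 10)) for t in detect_onsets(b).times]
        oracle = [
            i
            for i in range(4, len(b) - 3)
            if b[i] == 1 and not b[i - 4:i].any() and b[i:i + 4].all()
        ]
        agree += ours == oracle
    return {"agreement_pct": 100.0 * agree / n_sequences, "n": n_sequences}


# -- 3: mutual-information estimator ---------------------------------------

def mi_estimator_checks(seed: int = 0, n: int = 12000, n_seeds: int = 20) -> dict:
    x = np.repeat([0.0, 1.0, 2.0, 3.0], 250)
    b4 = BinningSpec(k=4, edges=np.linspace(-0.5, 3.5, 5))
    identity = mutual_information(x, x, b4, b4)
    bu = BinningSpec(k=4, edges=np.linspace(0, 1, 5))
    indep = []
    for s in range(n_seeds):
        rng = np.random.default_rng(_sub_seed(seed, s))
        indep.append(mutual_information(rng.uniform(size=n), rng.uniform(size=n), bu, bu))
    return {"identity_bits": identity, "independent_max_bits": float(np.max(indep)), "n": n}


# -- 4: functional-category recovery ---------------------------------------

def category_recovery(seed: int = 0, n_neurons: int = 200) -> dict:
    behavior = generate_behavior(
        BehaviorConfig(n_trials=20, condition="open_loop", rng_seed=_sub_seed(seed, 1))
    )
    rng = np.random.default_rng(_sub_seed(seed, 2))
    cats = ["rest", "run", "touch", "integrative"]
    specs = [NeuronSpec.make(cats[i % 4], rng) for i in range(n_neurons)]
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        session = generate_fluorescence(behavior, specs, rng_seed=_sub_seed(seed, 3))
    dff, _ = preprocess_stage(session)
    tl = segment_session(session)
    trial_index = session.trial_index_of_frames()
    correct = 0
    for i, spec in enumerate(specs):
        cm = bootstrap_condition_means(
            dff[i], tl.running, tl.touch, trial_index, seed=_sub_seed(seed, 10 + i)
        )
        correct += classify(cm).category == spec.category
    return {"recovery_pct": 100.0 * correct / n_neurons, "n": n_neurons}


# -- 5: speed-tuning recovery ----------------------------------------------

def _tuning_frames(rng, n=6000):
    speeds = np.concatenate([np.zeros(n // 3), rng.uniform(1.0, 15.0, n - n // 3)])
    rng.shuffle(speeds)
    return speeds


def tuning_recovery(seed: int = 0, n_bandpass: int = 50, n_noise: int = 100) -> dict:
    rng = np.random.default_rng(seed)
    speeds = _tuning_frames(rng)
    binning = equal_occupancy_bins(speeds, k=10)
    bin_width = float(np.median(np.diff(binning.edges)))
    errors = []
    for i in range(n_bandpass):
        smax = rng.uniform(3.0, 12.0)
        dff = 0.3 * np.exp(-((speeds - smax) ** 2) / 8.0) + rng.normal(0.0, 0.05, len(speeds))
        fit = fit_speed_tuning(speeds, dff, binning, seed=_sub_seed(seed, i))
        errors.append(abs(fit.s_max - smax))
    unclassified = 0
    for i in range(n_noise):
        sp = _tuning_frames(rng, n=2000)
        dff = rng.normal(0.0, 0.03, len(sp))
        fit = fit_speed_tuning(sp, dff, seed=_sub_seed(seed, 500 + i))
        unclassified += fit.tuning_class == "unclassified"
    return {
        "smax_median_error_binwidths": float(np.median(errors) / bin_width),
        "noise_unclassified_pct": 100.0 * unclassified / n_noise,
        "n": n_bandpass,
    }


# -- 6: encoding-model recovery --------------------------------------------

def _smooth(rng, n, scale=1.0):
    from scipy.ndimage import gaussian_filter1d

    return scale * gaussian_filter1d(rng.standard_normal(n), 5)


def encoding_recovery(seed: int = 0, n_driven: int = 20, n_noise: int = 20) -> dict:
    n = 1500
    rng = np.random.default_rng(seed)

    def predictors():
        return {
            "run_speed": np.abs(_smooth(rng, n, 5.0)),
            "texture_speed": np.abs(_smooth(rng, n, 5.0)),
            "whisk_envelope": np.abs(_smooth(rng, n, 2.0)),
        }

    # deterministic smooth functions of run speed: high explained variance
    driven_q = []
    top_count = 0
    for i in range(n_driven):
        preds = predictors()
        dff = np.tanh(preds["run_speed"] / 3.0) + rng.normal(0, 0.02, n)
        res = fit_encoding_model(dff, preds, seed=_sub_seed(seed, i))
        imp = all_shuffle_importances(res, seed=_sub_seed(seed, 100 + i))
        driven_q.append(res.q_bar)
        top_count += max(imp, key=imp.get) == "run_speed"
    noise_q = []
    for i in range(n_noise):
        res = fit_encoding_model(
            rng.standard_normal(n), predictors(), seed=_sub_seed(seed, 200 + i)
        )
        noise_q.append(res.q_bar)
    return {
        "driven_q_bar": float(np.mean(driven_q)),
        "runspeed_top_importance_count": int(top_count),
        "noise_q_bar": float(np.mean(noise_q)),
        "n": n_driven,
    }


# -- 7: forward/inverse consistency of the calcium model -------------------

def steady_state_consistency(seed: int = 0, rate_hz: float = 10.0, n_neurons: int = 100) -> dict:
    behavior = generate_behavior(
        BehaviorConfig(n_trials=10, condition="no_touch", run_bout_rate=0.0,
                       rng_seed=_sub_seed(seed, 1))
    )
    amp, tau = 0.10, 0.35
    specs = [
        NeuronSpec(baseline_rate=rate_hz, kernel_amplitude=amp, kernel_tau=tau, noise_sd=0.0)
        for _ in range(n_neurons)
    ]
    session = generate_fluorescence(behavior, specs, rng_seed=_sub_seed(seed, 2))
    dff = (session.fluo - 10.0) / 100.0 - 1.0
    mean_ss = float(dff[:, 50:].mean())
    expected = rate_hz * amp * tau
    recovered = rate_from_steady_state(mean_ss, amp, tau)
    return {
        "dff_relative_error_pct": 100.0 * abs(mean_ss - expected) / expected,
        "rate_relative_error_pct": 100.0 * abs(recovered - rate_hz) / rate_hz,
        "n": n_neurons,
    }


# -- 8: suppression of sustained vs transient touch responses --------------

def suppression_recovery(seed: int = 0, n_per_group: int = 25) -> dict:
    behavior = generate_behavior(
        BehaviorConfig(n_trials=25, condition="closed_loop", rng_seed=_sub_seed(seed, 1))
    )
    rng = np.random.default_rng(_sub_seed(seed, 2))
    specs = []
    for _ in range(n_per_group):
        specs.append(NeuronSpec.make("touch", rng))                       # sustained
    for _ in range(n_per_group):
        specs.append(NeuronSpec.make("touch", rng, touch_duration=1.0))   # 1-s transient
    session = generate_fluorescence(behavior, specs, rng_seed=_sub_seed(seed, 3))
    dff, stats = preprocess_stage(session)
    touch_ev, _ = touch_onsets(session.stage_moving_flag, session.contact_flag)
    supp = []
    for i in range(len(specs)):
        resp = align_and_average(dff[i], touch_ev)
        sigma = float(stats.loc[i, "sigma"])
        supp.append(touch_metrics(resp, sigma)[2])
    supp = np.array(supp)
    return {
        "sustained_median_pct": float(np.nanmedian(supp[:n_per_group])),
        "transient_median_pct": float(np.nanmedian(supp[n_per_group:])),
        "n": 2 * n_per_group,
    }


# -- 9: sound-control false-positive rate ----------------------------------

def control_false_positive_rate(seed: int = 0, n_neurons: int = 100) -> dict:
    """Noise neurons aligned to contactless stage motions (sound controls)
    in a no-touch session: fraction passing the 2-sigma criterion."""
    behavior = generate_behavior(
        BehaviorConfig(n_trials=30, condition="no_touch", rng_seed=_sub_seed(seed, 1))
    )
    rng = np.random.default_rng(_sub_seed(seed, 2))
    specs = [NeuronSpec.make("noise", rng) for _ in range(n_neurons)]
    session = generate_fluorescence(behavior, specs, rng_seed=_sub_seed(seed, 3))
    dff, stats = preprocess_stage(session)
    _, controls = touch_onsets(session.stage_moving_flag, session.contact_flag)
    config = PipelineConfig()
    fp = 0
    for i in range(n_neurons):
        resp = align_and_average(dff[i], controls)
        sigma = float(stats.loc[i, "sigma"])
        fp += touch_metrics(resp, sigma, config)[3]
    return {"false_positive_pct": 100.0 * fp / n_neurons, "n": n_neurons,
            "n_events": len(controls)}
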