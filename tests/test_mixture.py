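"""Constrained Gaussian mixtures: EM correctness, BIC, model selection."""

import shutil
import subprocess

import numpy as np
import pytest

from epiclust.cohort import CohortSpec, generate_cohort
from epiclust.mixture import (
    bic_mclust,
    fit_mixture,
    map_assign,
    n_free_params,
    select_model,
)


@pytest.mark.parametrize(
    "family, K, d, expected",
    [
        ("EII", 2, 2, 6),
        ("VII", 2, 2, 7),
        ("EEI", 2, 2, 7),
        ("EII", 1, 2, 3),
        ("EEI", 3, 4, 18),
    ],
)
def test_free_parameter_counts(family, K, d, expected):
    assert n_free_params(family, K, d) == expected


def test_unknown_family_rejected():
    with pytest.raises(ValueError):
        n_free_params("VVV", 2, 2)
    with pytest.raises(ValueError):
        fit_mixture(np.zeros((10, 2)), 2, "VVV")


def test_bic_mclust_values():
    """2*(-1427.85) - 6*ln(200) reproduces the published -2887.49."""
    assert bic_mclust(-1427.85, 6, 200) == pytest.approx(-2887.49, abs=0.01)
    assert bic_mclust(0.0, 0, 1) == 0.0
    assert bic_mclust(-1427.85, 7, 200) == pytest.approx(-2892.79, abs=0.01)


def test_k1_closed_form(tscores):
    """K=1 has an analytic MLE: mean = sample mean; EII variance is the
    average of the per-dimension MLE variances."""
    m = fit_mixture(tscores, 1, "EII", seed=0)
    np.testing.assert_allclose(m.means[0], tscores.mean(axis=0), rtol=1e-8)
    expected_var = tscores.var(axis=0).mean()  # ddof=0 (MLE)
    np.testing.assert_allclose(m.variances[0], expected_var, rtol=1e-6)
    eei = fit_mixture(tscores, 1, "EEI", seed=0)
    np.testing.assert_allclose(eei.variances[0], tscores.var(axis=0), rtol=1e-6)


@pytest.mark.parametrize("family", ["EII", "VII", "EEI"])
def test_em_loglik_is_monotone(tscores, family):
    m = fit_mixture(tscores, 2, family, seed=3)
    diffs = np.diff(m.loglik_path)
    assert (diffs >= -1e-7).all()
    assert m.bic == pytest.approx(bic_mclust(m.loglik, m.m, m.n), abs=1e-10)


def test_nesting_relations(tscores):
    """EII is a submodel of both VII and EEI: at the best of the shared
    restarts, the richer families cannot do worse."""
    eii = fit_mixture(tscores, 2, "EII", seed=5)
    vii = fit_mixture(tscores, 2, "VII", seed=5)
    eei = fit_mixture(tscores, 2, "EEI", seed=5)
    assert vii.loglik >= eii.loglik - 1e-6
    assert eei.loglik >= eii.loglik - 1e-6


def test_parameter_recovery_on_study_model(study_spec):
    """Across 20 cohorts the component means recover within 3 SE pooled."""
    errs = []
    for seed in range(20):
        table, _ = generate_cohort(study_spec, seed=seed)
        X = table[["internalizing", "externalizing"]].to_numpy(float)
        m = fit_mixture(X, 2, "EEI", seed=seed)
        errs.append(m.means - np.asarray(study_spec.component_means))
    mean_err = np.abs(np.mean(errs, axis=0))
    # SE of a component mean at n*w ~ 100 observations is about 0.65 T
    assert (mean_err < 3 * 7.0 / np.sqrt(100)).all()


def test_select_model_prefers_true_structure(study_spec):
    """On two well-separated spherical components, a 2-component spherical
    or diagonal model wins; on one Gaussian cloud, K=1 wins."""
    spec = CohortSpec(
        component_means=((45.0, 45.0), (65.0, 65.0)),
        component_sds=((5.0, 5.0), (5.0, 5.0)),
    )
    wins = 0
    for seed in range(5):
        table, _ = generate_cohort(spec, seed=100 + seed)
        X = table[["internalizing", "externalizing"]].to_numpy(float)
        best, ranking = select_model(X, K_range=range(1, 4), seed=seed)
        assert len(ranking) == 9
        if best.family == "EII" and best.K == 2:
            wins += 1
    assert wins >= 3  # EII/2 ranks first in the majority of replicates

    rng = np.random.default_rng(0)
    blob = rng.normal(50, 5, size=(200, 2))
    best, _ = select_model(blob, K_range=range(1, 3), seed=0)
    assert best.K == 1


def test_map_assignment_properties(study_spec):
    table, _ = generate_cohort(study_spec, seed=11)
    X = table[["internalizing", "externalizing"]].to_numpy(float)
    model = fit_mixture(X, 2, "EEI", seed=11)
    assign = map_assign(model, X)
    np.testing.assert_allclose(
        assign.responsibilities.sum(axis=1), 1.0, atol=1e-12
    )
    assert assign.names == ("LOW", "HIGH")
    assert model.means[0, 0] < model.means[1, 0]
    # a point exactly at a well-separated component mean is certain
    far = fit_mixture(
        np.vstack([np.random.default_rng(1).normal(0, 1, (100, 2)),
                   np.random.default_rng(2).normal(30, 1, (100, 2))]),
        2, "EII", seed=0,
    )
    at_mean = map_assign(far, far.means)
    assert at_mean.responsibilities[0, 0] > 0.99
    assert at_mean.responsibilities[1, 1] > 0.99
    # LOW share close to the generating weight
    share = (assign.labels == 0).mean()
    assert abs(share - 0.51) < 3 * np.sqrt(0.51 * 0.49 / len(X))


def test_vii_agrees_with_sklearn_spherical(tscores):
    """VII is sklearn's 'spherical' GaussianMixture; the two independent
    fitters reach the same maximized log-likelihood."""
    from sklearn.mixture import GaussianMixture

    ours = fit_mixture(tscores, 2, "VII", seed=0)
    gm = GaussianMixture(
        n_components=2, covariance_type="spherical", n_init=5,
        random_state=0, tol=1e-8, reg_covar=1e-6, max_iter=500,
    ).fit(tscores)
    sk_loglik = gm.score(tscores) * len(tscores)
    assert ours.loglik == pytest.approx(sk_loglik, abs=0.05)


def test_eii_agrees_with_r_mclust(tscores, tmp_path):
    """Cross-check against the R reference implementation of the same
    model family (EII, G=2): maximized log-likelihoods agree closely."""
    rscript = shutil.which("Rscript")
    assert rscript, "Rscript is expected on PATH"
    csv = tmp_path / "X.csv"
    np.savetxt(csv, tscores, delimiter=",", header="x,y", comments="")
    script = tmp_path / "fit.R"
    script.write_text(
        "suppressMessages(library(mclust))\n"
        f"X <- read.csv('{csv}')\n"
        "fit <- Mclust(X, G=2, modelNames='EII', verbose=FALSE)\n"
        "cat(sprintf('%.6f', fit$loglik))\n"
    )
    out = subprocess.run(
        [rscript, str(script)], capture_output=True, text=True, timeout=300
    )
    assert out.returncode == 0, out.stderr
    r_loglik = float(out.stdout.strip())
    ours = fit_mixture(tscores, 2, "EII", seed=0)
    assert ours.loglik == pytest.approx(r_loglik, abs=0.5)
    assert ours.loglik >= r_loglik - 1e-3  # our restarts reach at least R's optimum
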