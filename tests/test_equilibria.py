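import numpy as np
import pytest

from tumor_immune import (
    BranchInvalidError,
    cd8_from_lysis,
    classify,
    cytokine_tumor_candidates,
    enumerate_equilibria,
    equilibria_table,
    jacobian,
    lysis_fraction_D,
    nk_at_tumor,
    nonzero_cytokine_equilibria,
    tumor_free_stable,
    zero_cytokine_equilibria,
    zero_tumor_eigenvalues,
    zero_tumor_equilibrium,
)


# ---------------------------------------------------------------------------
# zero-tumor branch, closed forms
# ---------------------------------------------------------------------------

def test_zero_tumor_equilibrium_both_patients(p1, p2):
    for params in (p1, p2):
        pt = zero_tumor_equilibrium(params)
        assert pt.T == pt.L == pt.Y == pt.I == 0.0
        assert pt.N == pytest.approx(315534, rel=1e-6)
        assert pt.C == pytest.approx(6.25e10, rel=1e-12)
        assert pt.residual < 1e-10


def test_zero_tumor_equilibrium_unit_ratio(p1):
    params = p1.replace(e=1e-3, alpha=2.0, f=1e-3, beta=2.0)  # e*alpha == f*beta
    assert zero_tumor_equilibrium(params).N == pytest.approx(1.0, rel=1e-12)


def test_zero_tumor_eigenvalues_closed_form(p1):
    lam = zero_tumor_eigenvalues(p1)
    assert lam[1:] == pytest.approx([-0.0412, -0.204, -0.1, -0.012, -10.0], rel=1e-12)
    assert lam[0] > 0  # recurrence condition violated at baseline: unstable
    assert lam[0] == pytest.approx(p1.a - p1.c * p1.e * p1.alpha / (p1.f * p1.beta))


def test_tumor_free_thresholds(p1):
    stable, a_crit, c_crit = tumor_free_stable(p1)
    assert not stable
    assert a_crit == pytest.approx(2.02257e-5, rel=2.5e-6)  # half-ulp at 6 digits
    assert c_crit == pytest.approx(1.365e-6, rel=2e-3)
    # below the just-computed growth threshold the tumor-free state is stable
    assert tumor_free_stable(p1.replace(a=1e-5))[0]
    # the leading eigenvalue flips sign exactly at the threshold
    assert zero_tumor_eigenvalues(p1.replace(a=a_crit))[0] == pytest.approx(0.0, abs=1e-18)


# ---------------------------------------------------------------------------
# reduced relations
# ---------------------------------------------------------------------------

def test_nk_at_tumor_reference_values(p1, p2):
    assert nk_at_tumor(1.90609e7, p1) == pytest.approx(199.335, rel=1e-4)
    assert nk_at_tumor(1.27423e6, p2) == pytest.approx(2824.14, rel=1e-4)
    # the zero-tumor limit recovers the closed-form NK level
    assert nk_at_tumor(0.0, p1) == pytest.approx(p1.e * p1.alpha / (p1.f * p1.beta))


def test_nk_at_tumor_invalid_branch():
    from tumor_immune import patient1
    params = patient1().replace(g=10.0)  # recruitment overwhelms turnover
    with pytest.raises(BranchInvalidError):
        nk_at_tumor(1e5, params)


def test_cd8_from_lysis_inversion(p1):
    assert cd8_from_lysis(1e6, 0.0, p1) == 0.0
    # half-saturation inverts to L = s^(1/l) * T
    assert cd8_from_lysis(1e6, p1.d / 2, p1) == pytest.approx(
        p1.s ** (1 / p1.l) * 1e6, rel=1e-12)
    with pytest.raises(BranchInvalidError):
        cd8_from_lysis(1e6, p1.d, p1)
    # round trip over a (T, D) grid
    for T in np.logspace(2, 9, 12):
        for D in np.linspace(0.01, 0.99, 9) * p1.d:
            L = cd8_from_lysis(T, D, p1)
            assert lysis_fraction_D(T, L, p1) == pytest.approx(D, rel=1e-10)


# ---------------------------------------------------------------------------
# zero-cytokine branch
# ---------------------------------------------------------------------------

def test_zero_cytokine_equilibria_reference_points(p1, p2):
    pts1 = zero_cytokine_equilibria(p1)
    assert len(pts1) == 1
    assert pts1[0].T == pytest.approx(1.90609e7, rel=1e-4)
    assert pts1[0].N == pytest.approx(199.335, rel=1e-4)
    assert pts1[0].L == pytest.approx(2.82461e6, rel=1e-4)
    assert pts1[0].Y == 0.0 and pts1[0].I == 0.0
    assert pts1[0].C == pytest.approx(6.25e10, rel=1e-12)

    pts2 = zero_cytokine_equilibria(p2)
    assert len(pts2) == 1
    assert pts2[0].T == pytest.approx(1.27423e6, rel=1e-4)
    assert pts2[0].N == pytest.approx(2824.14, rel=1e-4)
    assert pts2[0].L == pytest.approx(450073, rel=1e-4)


def test_zero_cytokine_branch_invalid_everywhere(p1):
    # NK kill so strong that the demanded lysis rate is negative at every T
    assert zero_cytokine_equilibria(p1.replace(c=0.1)) == []


def test_zero_cytokine_grid_refinement(p1):
    coarse = zero_cytokine_equilibria(p1, t_grid=(1.0, 1.0 / p1.b, 2000))
    fine = zero_cytokine_equilibria(p1, t_grid=(1.0, 1.0 / p1.b, 4000))
    assert len(coarse) == len(fine) == 1
    for name in ("T", "N", "L"):
        a, b = getattr(coarse[0], name), getattr(fine[0], name)
        assert abs(a - b) / b < 1e-4


def test_zero_cytokine_against_quadratic_oracle(p1, p2):
    """Brute-force check: with the lysis demand fixed by the tumor balance,
    the CD8+T balance is a quadratic in L whose positive root must meet the
    lysis inversion; scanning that difference reproduces the same roots."""
    for params, expected_T in ((p1, 1.90609e7), (p2, 1.27423e6)):
        pr = params
        C = pr.alpha / pr.beta

        def mismatch(T):
            den = pr.beta * (pr.p * T**3 + (pr.f - pr.g) * T**2
                             + pr.p * pr.h * T + pr.f * pr.h)
            if den <= 0:
                return None
            N = pr.e * pr.alpha * (pr.h + T * T) / den
            D = pr.a * (1 - pr.b * T) - pr.c * N
            if not 0 <= D < pr.d:
                return None
            L_lysis = (pr.s * D / (pr.d - D)) ** (1 / pr.l) * T
            DT2 = (D * T) ** 2
            lin = pr.m - pr.j * DT2 / (pr.k + DT2) + pr.q * T
            const = -(pr.r1 * N + pr.r2 * C) * T
            a2 = pr.u * N
            disc = lin * lin - 4 * a2 * const
            L_balance = (-lin + np.sqrt(disc)) / (2 * a2)  # positive root kept
            return L_lysis - L_balance

        Ts = np.logspace(0, np.log10(1 / pr.b), 20000)
        vals = np.array([v if (v := mismatch(T)) is not None else np.nan for T in Ts])
        ok = ~np.isnan(vals)
        sign_changes = np.flatnonzero(np.diff(np.sign(vals[ok])) != 0)
        assert len(sign_changes) == 1
        idx = np.flatnonzero(ok)[sign_changes[0]]
        assert Ts[idx] <= expected_T * 1.001 and expected_T * 0.999 <= Ts[idx + 1]


# ---------------------------------------------------------------------------
# nonzero-cytokine branch
# ---------------------------------------------------------------------------

def test_cytokine_tumor_candidates(p1, p2):
    roots2 = cytokine_tumor_candidates(p2)
    assert any(abs(r - 3.50643e6) / 3.50643e6 < 1e-4 for r in roots2)
    assert any(1e2 < r < 1e4 for r in roots2)  # second positive root
    # the cubic uses only CD4/cytokine constants, equal for both patients
    assert cytokine_tumor_candidates(p1) == pytest.approx(roots2, rel=1e-12)
    # companion-matrix oracle
    c2 = (p2.alpha1 + p2.alpha2 + p2.mu1 / p2.delta2
          - p2.beta1 * p2.beta2 / (p2.delta2 * p2.mu_i))
    c1 = p2.alpha1 * p2.alpha2 + p2.mu1 * (p2.alpha1 + p2.alpha2) / p2.delta2
    c0 = p2.mu1 * p2.alpha1 * p2.alpha2 / p2.delta2
    poly_roots = sorted(r.real for r in np.roots([1, c2, c1, c0]) if r.real > 0)
    assert roots2 == pytest.approx(poly_roots, rel=1e-8)


def test_nonzero_cytokine_equilibria_patient2(p2):
    pts = nonzero_cytokine_equilibria(p2)
    assert len(pts) == 1
    pt = pts[0]
    assert pt.T == pytest.approx(3.50643e6, rel=1e-4)
    assert pt.N == pytest.approx(1030.37, rel=1e-4)
    assert pt.L == pytest.approx(952787, rel=1e-4)
    assert pt.Y == pytest.approx(4.55393e6, rel=1e-4)
    assert pt.I == pytest.approx(2.45842e6, rel=1e-4)
    # cytokine-balance identity used in the construction holds exactly
    assert pt.Y * p2.beta2 * pt.T / (p2.alpha2 + pt.T) == pytest.approx(
        p2.mu_i * pt.I, rel=1e-8)


def test_nonzero_cytokine_empty_for_patient1(p1):
    assert nonzero_cytokine_equilibria(p1) == []


def test_all_equilibria_have_small_residual(p1, p2):
    for params in (p1, p2):
        for pt in enumerate_equilibria(params):
            assert pt.residual < 1e-6


# ---------------------------------------------------------------------------
# linearization and verdicts
# ---------------------------------------------------------------------------

def test_jacobian_zero_tumor_matches_analytic(p1):
    pt = zero_tumor_equilibrium(p1)
    J = jacobian(pt.state(), p1)
    a_eff = p1.a - p1.c * p1.e * p1.alpha / (p1.f * p1.beta)
    assert J[0, 0] == pytest.approx(a_eff, rel=1e-6)
    assert J[1, 1] == pytest.approx(-p1.f, rel=1e-6)
    assert J[1, 4] == pytest.approx(p1.e, rel=1e-6)
    assert J[4, 4] == pytest.approx(-p1.beta, rel=1e-6)
    # eigenvalues agree with the closed forms
    eig = np.sort(np.linalg.eigvals(J).real)
    lam = np.sort(zero_tumor_eigenvalues(p1))
    assert eig == pytest.approx(lam, rel=1e-6, abs=1e-10)


def test_jacobian_constant_rhs_is_zero(monkeypatch):
    import tumor_immune.equilibria as eq

    const = np.arange(6, dtype=float)
    monkeypatch.setattr(eq, "rhs_untreated", lambda state, params: const)
    assert np.array_equal(eq.jacobian(np.ones(6), None), np.zeros((6, 6)))


def test_classify_reference_verdicts(p1, p2):
    for params in (p1, p2):
        for pt in enumerate_equilibria(params):
            assert classify(pt, params).verdict == "unstable"
    # tumor-free state below the growth threshold is stable
    params = p1.replace(a=1e-5)
    assert classify(zero_tumor_equilibrium(params), params).verdict == "stable"


def test_classify_agrees_with_closed_form_over_random_parameters(p1, rng):
    """Numerical-Jacobian verdict at the tumor-free state matches the
    closed-form recurrence condition for 200 randomized parameter sets."""
    from tumor_immune.parameters import PARAM_FIELDS
    agree = 0
    for _ in range(200):
        factors = rng.uniform(0.5, 2.0, size=len(PARAM_FIELDS))
        params = p1.replace(**{name: getattr(p1, name) * fac
                               for name, fac in zip(PARAM_FIELDS, factors)})
        stable, _, _ = tumor_free_stable(params)
        report = classify(zero_tumor_equilibrium(params), params)
        if report.verdict == "marginal":
            continue
        assert (report.verdict == "stable") == stable
        agree += 1
    assert agree >= 195  # marginal band should almost never trigger


def test_equilibria_table_shape(p2):
    df = equilibria_table(p2)
    assert list(df["branch"]) == ["zero_tumor", "nonzero_tumor_zero_cytokine",
                                  "nonzero_tumor_nonzero_cytokine"]
    assert set(df["verdict"]) == {"unstable"}
    assert {"T", "N", "L", "Y", "C", "I", "eigenvalues"} <= set(df.columns)
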