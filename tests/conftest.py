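import datetime as dt

import pytest

import breaktracer as bt


@pytest.fixture(scope="session")
def toy_genome():
    return bt.make_toy_genome(seed=11)


@pytest.fixture(scope="session")
def implanted(toy_genome):
    return bt.implant_translocation(toy_genome, 2500, 2600)


@pytest.fixture(scope="session")
def junction_ref(toy_genome, implanted):
    return bt.build_junction(implanted.spec, toy_genome.sequences, flank_len=300)


@pytest.fixture(scope="session")
def assay(junction_ref):
    return bt.design_assay(junction_ref)


def make_result(
    n_positive,
    n_total=40000,
    sample="S",
    assay_id="fusion",
    qc_flags=(),
    volumes=None,
):
    """Build a QuantResult from pooled droplet counts via the real pipeline."""
    volumes = volumes or bt.VolumesConfig()
    est = bt.poisson_concentration(n_positive, n_total, volumes)
    cpm = bt.copies_per_ml_plasma(est.conc_copies_per_uL, volumes)
    lod, _ = bt.limit_of_detection(n_total, volumes)
    return bt.QuantResult(
        sample_id=sample,
        assay_id=assay_id,
        n_total=n_total,
        n_positive=n_positive,
        lam=est.lam,
        conc_copies_per_uL=est.conc_copies_per_uL,
        conc_ci95=est.conc_ci95,
        copies_per_mL_plasma=cpm,
        copies_per_mL_ci95=(
            bt.copies_per_ml_plasma(est.conc_ci95[0], volumes),
            bt.copies_per_ml_plasma(est.conc_ci95[1], volumes),
        ),
        lod_copies_per_mL=lod,
        detectability=bt.detectability(n_positive),
        qc_flags=list(qc_flags),
    )


def series_from_counts(counts, start=dt.date(2024, 1, 1), **kwargs):
    """A patient series whose timepoints carry the given pooled positives."""
    tps = [
        bt.TimePoint(
            patient_id="P1",
            date=start + dt.timedelta(days=30 * i),
            result=make_result(k, **kwargs),
        )
        for i, k in enumerate(counts)
    ]
    return bt.build_series(tps)
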