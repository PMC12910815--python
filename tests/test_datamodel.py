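"""Container validation and tab-separated I/O round trips."""

import numpy as np
import pandas as pd
import pytest

from conftest import make_paired
from pairednb.datamodel import (McmcConfig, ModelSpec, PosteriorDraws,
                                read_paired_table, write_count_table,
                                write_posterior_summary)


@pytest.fixture
def table_files(tmp_path):
    """Two 3-taxa x 4-sample tables plus metadata; sample D only in site 1."""
    samples = ["A", "B", "C", "D"]
    t1 = pd.DataFrame([[5, 0, 2, 1], [3, 7, 0, 4], [2, 3, 1, 5]],
                      index=["Lactobacillus", "Gardnerella", "Prevotella"],
                      columns=samples)
    t2 = pd.DataFrame([[1, 4, 0], [0, 2, 6], [9, 1, 1]],
                      index=["Lactobacillus", "Gardnerella", "Prevotella"],
                      columns=["A", "B", "C"])
    meta = pd.DataFrame({"age": [61.0, 45.0, 70.0, 52.0],
                         "bmi": [24.0, 31.0, 27.0, 22.0],
                         "group": ["pre", "post", "post", "pre"]},
                        index=pd.Index(samples, name="sample"))
    p1, p2, pm = (tmp_path / f for f in
                  ("site1.tsv", "site2.tsv", "meta.tsv"))
    t1.to_csv(p1, sep="\t")
    t2.to_csv(p2, sep="\t")
    meta.to_csv(pm, sep="\t")
    return p1, p2, pm, t1, t2


def test_read_paired_table_depths_are_column_sums(table_files):
    p1, p2, pm, t1, t2 = table_files
    d = read_paired_table(p1, p2, pm, "Lactobacillus",
                          covariate_columns=["age", "bmi"])
    assert d.n == 4
    assert np.array_equal(d.depths[0], t1.sum(axis=0).to_numpy())
    assert np.array_equal(d.counts[0], t1.loc["Lactobacillus"].to_numpy())
    # depth over a taxon subset
    d9 = read_paired_table(p1, p2, pm, "Lactobacillus",
                           covariate_columns=["age"],
                           depth_taxa=["Lactobacillus", "Gardnerella"])
    assert np.array_equal(
        d9.depths[0], t1.loc[["Lactobacillus", "Gardnerella"]].sum().to_numpy())


def test_read_paired_table_unbalanced_mask(table_files):
    p1, p2, pm, *_ = table_files
    d = read_paired_table(p1, p2, pm, "Gardnerella",
                          covariate_columns=["age"])
    assert d.present[0].all()
    assert list(d.present[1]) == [True, True, True, False]


def test_read_paired_table_group_column(table_files):
    p1, p2, pm, *_ = table_files
    d = read_paired_table(p1, p2, pm, "Prevotella",
                          covariate_columns=["age"], group_column="group")
    assert set(d.group_labels) == {1, 2}
    assert d.n_groups == 2


def test_read_paired_table_errors(table_files, tmp_path):
    p1, p2, pm, t1, _ = table_files
    with pytest.raises(KeyError):
        read_paired_table(p1, p2, pm, "Escherichia")
    bad = t1.copy()
    bad.iloc[0, 0] = -3
    pbad = tmp_path / "bad.tsv"
    bad.to_csv(pbad, sep="\t")
    with pytest.raises(ValueError, match="non-negative"):
        read_paired_table(pbad, p2, pm, "Lactobacillus")
    meta_short = pd.read_csv(pm, sep="\t", index_col=0).iloc[:2]
    pms = tmp_path / "meta_short.tsv"
    meta_short.to_csv(pms, sep="\t")
    with pytest.raises(ValueError, match="missing from metadata"):
        read_paired_table(p1, p2, pms, "Lactobacillus")


def test_count_table_round_trip(tmp_path, table_files):
    from pairednb.datamodel import read_count_table
    *_, t1, _ = table_files
    path = tmp_path / "rt.tsv"
    write_count_table(t1, path)
    back = read_count_table(path)
    assert back.equals(t1.astype(np.int64))
    # transpose option
    t1.T.to_csv(tmp_path / "tr.tsv", sep="\t")
    assert read_count_table(tmp_path / "tr.tsv", transpose=True).equals(
        t1.astype(np.int64))


def test_validation_invariants():
    with pytest.raises(ValueError, match="exceeds"):
        make_paired([20, 1], [0, 0], [10, 10], [5, 5])
    with pytest.raises(ValueError, match="negative"):
        make_paired([-1, 1], [0, 0], [10, 10], [5, 5])
    with pytest.raises(ValueError, match="two samples"):
        make_paired([1], [0], [10], [5])
    with pytest.raises(ValueError, match="intercept"):
        make_paired([1, 1], [0, 0], [10, 10], [5, 5],
                    X=np.array([[2.0], [2.0]]))
    with pytest.raises(ValueError, match="contiguous"):
        make_paired([1, 1], [0, 0], [10, 10], [5, 5],
                    groups=np.array([1, 3]))


def test_model_spec_validation():
    with pytest.raises(ValueError):
        ModelSpec(model="XNBM")
    with pytest.raises(ValueError):
        ModelSpec(model="JNBM_Mix", L=1)
    with pytest.raises(ValueError):
        ModelSpec(a_phi2=-0.1)
    with pytest.raises(ValueError):
        McmcConfig(iterations=100, burnin=100)
    spec = ModelSpec(model="JNBM_Mix", L=4)
    assert np.allclose(spec.p_nu, 0.25)


def _const_draws(value, B=100):
    return PosteriorDraws(beta=np.full((B, 2, 1), value),
                          alpha=np.ones((B, 2)), tau2=np.ones((B, 2)),
                          model="SNBM")


def test_posterior_summary_constant_and_two_point(tmp_path):
    out = write_posterior_summary(_const_draws(1.0), tmp_path / "s.tsv")
    row = out[out.parameter == "beta[1,1]"].iloc[0]
    assert row["mean"] == 1.0 and row["sd"] == 0.0
    d = _const_draws(0.0)
    d.beta[::2, :, :] = 2.0
    out = write_posterior_summary(d, tmp_path / "s2.tsv")
    assert out[out.parameter == "beta[1,1]"].iloc[0]["mean"] == 1.0


def test_posterior_summary_empty_trace_rejected(tmp_path):
    with pytest.raises(ValueError, match="empty"):
        write_posterior_summary(_const_draws(1.0, B=0), tmp_path / "x.tsv")


def test_summary_byte_identical_across_reruns(tmp_path):
    """Seeded sampler run -> summary file identical on rerun."""
    from pairednb.sampler import run_gibbs
    data = make_paired([3, 0, 9, 2], [1, 5, 0, 2],
                       [20, 15, 40, 9], [12, 30, 7, 9])
    spec = ModelSpec(model="JNBM", mcmc=McmcConfig(iterations=300,
                                                   burnin=100, thin=2,
                                                   seed=9))
    for tag in ("a", "b"):
        write_posterior_summary(run_gibbs(data, spec),
                                tmp_path / f"{tag}.tsv")
    assert (tmp_path / "a.tsv").read_bytes() == (tmp_path / "b.tsv").read_bytes()
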