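import numpy as np
import pytest

from dapnet import ExpressionDataset


def make_dataset(values, labels, gene_ids=None, sample_ids=None, annotations=None):
    values = np.asarray(values, dtype=float)
    g, s = values.shape
    return ExpressionDataset(
        gene_ids=gene_ids or [f"g{i}" for i in range(g)],
        sample_ids=sample_ids or [f"s{j}" for j in range(s)],
        class_labels=np.asarray(labels),
        values=values,
        annotations=annotations or {},
    )


@pytest.fixture
def dataset_factory():
    return make_dataset


@pytest.fixture
def toy_dataset():
    """6 genes x 20 samples, two classes, correlated pair (g0, g1) in class A only."""
    rng = np.random.default_rng(42)
    n = 10
    x = rng.normal(8, 1, 2 * n)
    y = np.empty_like(x)
    r = 0.95
    y[:n] = r * (x[:n] - 8) + np.sqrt(1 - r * r) * rng.normal(0, 1, n) + 8
    y[n:] = rng.normal(8, 1, n)
    rest = rng.normal(8, 1, (4, 2 * n))
    values = np.vstack([x, y, rest])
    return make_dataset(values, ["A"] * n + ["B"] * n)


@pytest.fixture
def expression_files(tmp_path):
    """Small on-disk expression + label TSVs (3 genes x 4 samples, one NA)."""
    expr = tmp_path / "expr.tsv"
    expr.write_text(
        "gene_id\tdescription\ts1\ts2\ts3\ts4\n"
        "g1\talpha\t1.0\t2.0\t3.0\t4.0\n"
        "g2\tbeta\t2.0\tNA\t6.0\t8.0\n"
        "g3\tgamma\t5.5\t5.0\t4.5\t4.0\n"
    )
    labels = tmp_path / "labels.tsv"
    labels.write_text("sample_id\tclass\ns1\tA\ns2\tA\ns3\tB\ns4\tB\n")
    return expr, labels
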