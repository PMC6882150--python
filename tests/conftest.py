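import itertools

import pytest
from hypothesis import settings as hyp_settings

import mprclust as m

hyp_settings.register_profile("deterministic", derandomize=True, deadline=None)
hyp_settings.load_profile("deterministic")


def graph_of(inst):
    return m.build_recon_graph(inst, m.compute_dp(inst))


def small_instances(n, seed0=0, max_leaves=4):
    """Deterministic batch of small random instances for oracle checks."""
    out = []
    for seed in range(seed0, seed0 + n):
        cfg = m.GeneratorConfig(
            seed=seed,
            n_species_leaves=2 + seed % (max_leaves - 1),
            n_gene_leaves=2 + (seed // 3) % (max_leaves - 1),
        )
        out.append(m.random_instance(cfg))
    return out


def brute_pair_distance_mean(travs):
    from fractions import Fraction

    sets = [t.events for t in travs]
    pairs = list(itertools.combinations(sets, 2))
    if not pairs:
        return Fraction(0)
    return Fraction(sum(len(a ^ b) for a, b in pairs), len(pairs))


@pytest.fixture(scope="session")
def toy3():
    return m.fixture("toy3")


@pytest.fixture(scope="session")
def toy3_graph(toy3):
    return graph_of(toy3)


@pytest.fixture()
def toy3_files(tmp_path, toy3):
    from mprclust.instance import write_newick

    s = tmp_path / "species.nwk"
    g = tmp_path / "gene.nwk"
    mp = tmp_path / "mapping.tsv"
    s.write_text(write_newick(toy3.species_tree) + "\n")
    g.write_text(write_newick(toy3.gene_tree) + "\n")
    mp.write_text("".join(f"{a}\t{b}\n" for a, b in toy3.mapping.items()))
    return {"species": s, "gene": g, "mapping": mp}
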