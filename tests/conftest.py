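import numpy as np
import pytest

import lipoflex as lf


@pytest.fixture(scope="session")
def default_params():
    return lf.load_params()


@pytest.fixture(scope="session")
def toy():
    return lf.make_toy_protein()


@pytest.fixture(scope="session")
def small_toy():
    return lf.make_toy_protein(lf.ToySpec(n_strands=4, n_strand_res=4,
                                          n_helix_res=6))


@pytest.fixture()
def tripeptide():
    return lf.make_peptide("AYA", "extended")


def brute_force_hint(model, params, assignment):
    """Independent all-pairs reference for the hydropathic score: explicit
    double loop, graph distances via networkx, classification re-derived
    from the documented rules."""
    import networkx as nx

    n = len(model)
    g = nx.Graph()
    g.add_nodes_from(range(n))
    g.add_edges_from(model.covalent_bonds)
    coords = model.coords
    roles = assignment.hbond_role
    classes = assignment.polarity_class

    # donor hydrogens
    h_parent = {}
    for i, j in model.covalent_bonds:
        for h, p in ((i, j), (j, i)):
            if model.atoms[h].element == "H" and model.atoms[p].element != "H":
                h_parent[h] = p

    def hbond(i, j):
        def geom(d, h, a):
            v_ha = coords[a] - coords[h]
            if np.linalg.norm(v_ha) > params.hbond_h_acceptor_max:
                return False
            v_hd = coords[d] - coords[h]
            cosang = v_hd @ v_ha / (np.linalg.norm(v_hd) * np.linalg.norm(v_ha))
            return np.degrees(np.arccos(np.clip(cosang, -1, 1))) >= params.hbond_angle_min

        ei = model.atoms[i].element
        ej = model.atoms[j].element
        if ei == "H" and ej == "H":
            return False
        if ei == "H" or ej == "H":
            h, other = (i, j) if ei == "H" else (j, i)
            d = h_parent.get(h)
            if d is None or model.atoms[d].element not in "NOS":
                return False
            return roles[d] in ("donor", "both") and roles[other] in ("acceptor", "both") \
                and geom(d, h, other)
        for d, a in ((i, j), (j, i)):
            if roles[d] in ("donor", "both") and roles[a] in ("acceptor", "both"):
                for h, p in h_parent.items():
                    if p == d and geom(d, h, a):
                        return True
        return False

    total = 0.0
    components = {k: 0.0 for k in ("hydrogen-bond", "electrostatic-favorable",
                                   "hydrophobic", "electrostatic-unfavorable",
                                   "desolvation")}
    for i in range(n):
        for j in range(i + 1, n):
            r = float(np.linalg.norm(coords[i] - coords[j]))
            if r > params.cutoff:
                continue
            try:
                dist = nx.shortest_path_length(g, i, j)
            except nx.NetworkXNoPath:
                dist = 10 ** 9
            if dist <= params.exclusion_bond_depth:
                continue
            raw = (assignment.sasa[i] * assignment.a[i] * assignment.sasa[j]
                   * assignment.a[j] * np.exp(-r / params.decay_length))
            if hbond(i, j):
                k = "hydrogen-bond"
            elif {classes[i], classes[j]} == {"acid", "base"}:
                k = "electrostatic-favorable"
            elif classes[i] == classes[j] and classes[i] in ("acid", "base"):
                k = "electrostatic-unfavorable"
                raw = -abs(raw)
            elif assignment.a[i] > 0 and assignment.a[j] > 0:
                k = "hydrophobic"
            elif assignment.a[i] * assignment.a[j] < 0:
                k = "desolvation"
            else:
                k = "electrostatic-favorable"
            total += raw
            components[k] += raw
    return total, components
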