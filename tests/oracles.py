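"""Independent brute-force oracles used to verify the implementation.

Everything here is written in plain Python loops with the `math` module,
deliberately sharing no code path with the vectorised package internals.
"""

import math

COULOMB = 138.935458


def oracle_pair_force(pos_a, pos_b, q_a, q_b, sigma, epsilon, box,
                      r_cut=1.2, r_switch=1.0):
    """Truncated-Coulomb + force-switched-LJ pair force, scalar loops."""
    d = [pos_a[i] - pos_b[i]
         - box[i] * round((pos_a[i] - pos_b[i]) / box[i]) for i in range(3)]
    r = math.sqrt(sum(x * x for x in d))
    if r > r_cut:
        return [0.0, 0.0, 0.0]
    f = COULOMB * q_a * q_b / r**2
    for c, p in ((4 * epsilon * sigma**12, 12), (-4 * epsilon * sigma**6, 6)):
        a = p * c
        f += a / r ** (p + 1)
        if r > r_switch:
            dr = r_cut - r_switch
            aa = -a * ((p + 4) * r_cut - (p + 1) * r_switch) / (
                r_cut ** (p + 2) * dr**2)
            bb = a * ((p + 3) * r_cut - (p + 1) * r_switch) / (
                r_cut ** (p + 2) * dr**3)
            f += aa * (r - r_switch) ** 2 + bb * (r - r_switch) ** 3
    return [f / r * x for x in d]


def oracle_punctual_stress(system, coords, r_cut=1.2, r_switch=1.0):
    """Naive quadruple loop: residues x lipids x atoms x atoms."""
    protein_residues = sorted({int(system.residue_index[i])
                               for i in range(system.n_atoms)
                               if system.group_tag[i] == "protein"})
    lipid_mols = sorted({int(system.molecule_index[i])
                         for i in range(system.n_atoms)
                         if system.group_tag[i] == "lipid"})
    ps = []
    for res in protein_residues:
        total = 0.0
        res_atoms = [i for i in range(system.n_atoms)
                     if system.residue_index[i] == res]
        for mol in lipid_mols:
            mol_atoms = [i for i in range(system.n_atoms)
                         if system.molecule_index[i] == mol
                         and system.group_tag[i] == "lipid"]
            fx = fy = fz = 0.0
            for ia in res_atoms:
                for ib in mol_atoms:
                    sigma = 0.5 * (system.lj_sigma[ia] + system.lj_sigma[ib])
                    eps = math.sqrt(system.lj_epsilon[ia]
                                    * system.lj_epsilon[ib])
                    f = oracle_pair_force(coords[ia], coords[ib],
                                          system.charges[ia],
                                          system.charges[ib],
                                          sigma, eps, system.box,
                                          r_cut, r_switch)
                    fx += f[0]; fy += f[1]; fz += f[2]
            total += math.sqrt(fx * fx + fy * fy + fz * fz)
        ps.append(total)
    return ps


def oracle_auc(scores, labels):
    """Pair-count Mann-Whitney AUC: wins 1, ties 1/2."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    wins = 0.0
    for sp in pos:
        for sn in neg:
            if sp > sn:
                wins += 1.0
            elif sp == sn:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def oracle_pls_predict(model, X):
    """Component-by-component PLS prediction (no composed coefficients)."""
    preds = []
    for row in X:
        xc = [row[j] - model.x_mean[j] for j in range(model.n_features)]
        y = model.y_mean
        for k in range(model.n_components):
            t = sum(xc[j] * model.weight_vectors[j, k]
                    for j in range(model.n_features))
            y += model.y_loadings[k] * t
            for j in range(model.n_features):
                xc[j] -= t * model.loadings[j, k]
        preds.append(y)
    return preds


def oracle_ols_predict(X, y, X_new):
    """Ordinary least squares on mean-centred data via normal equations."""
    import numpy as np

    X = np.asarray(X, float); y = np.asarray(y, float)
    xm = X.mean(axis=0); ym = y.mean()
    Xc = X - xm
    beta = np.linalg.solve(Xc.T @ Xc, Xc.T @ (y - ym))
    return ym + (np.asarray(X_new, float) - xm) @ beta
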