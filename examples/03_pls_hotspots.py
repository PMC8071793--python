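"""Recovering force hotspots with PLS from a synthetic ensemble.

A small ensemble plants 6 hotspot features (mixed signs) driving a
latent down->up transition under heavy per-frame noise; PLS regression
of the observable on the features recovers the planted coefficient
pattern and ranks the hotspots.
"""

import numpy as np

import forcemode as fm

spec = fm.SyntheticEnsembleSpec(n_replicas_transition=4,
                                n_replicas_control=2, n_frames=200,
                                n_features=60, n_hotspots=6,
                                noise_sigma=2.0, transition_window=(40, 160),
                                seed=7)
ens = fm.generate_force_ensemble(spec)
X = np.vstack(ens.features)
y = np.concatenate(ens.observable)

model = fm.fit_pls(X, y, n_components=2)
coef = model.coefficient_vector
tc = ens.true_coefficients
cosine = coef @ tc / (np.linalg.norm(coef) * np.linalg.norm(tc))
print(f"cosine(estimated, planted coefficients) = {cosine:.3f}")

pos, neg = fm.top_residues(coef, ens.residue_ids(), k=3)
print("\nmost positive coefficients (stress grows through the transition):")
print(pos.to_string(index=False))
print("\nmost negative coefficients (stress drops through the transition):")
print(neg.to_string(index=False))
print("\nplanted hotspots:",
      [ens.residue_ids()[i] for i in np.flatnonzero(tc != 0)])

contrib = fm.component_contribution(model, X, y)
print(f"\nfirst-component contribution: {100 * contrib[0]:.1f}% "
      "(a single collective force mode carries the signal)")
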