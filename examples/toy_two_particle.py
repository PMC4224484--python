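"""Two oscillating particles: what mode-level correlation sees that DCC misses.

Both particles share a sinusoidal x-oscillation; particle 1 drifts 1.94 A
along y half-way through the 1,000-step trajectory.  The drift inflates
particle 1's displacement variance, so the conventional DCC between the
particles drops to ~0.58 even though their fast motion is almost perfectly
coupled.  Decomposing particle 1 into Gaussian modes (one per y-site) and
correlating mode pairs recovers the coupling: every surviving mode pair
scores ~0.97.
"""

import mdcc

traj = mdcc.simulate_toy(seed=1)
print(f"trajectory: {traj.n_frames} steps, {traj.n_atoms} particles")

expect = mdcc.toy_closed_forms()
print(f"closed-form expectation: DCC {expect['dcc']:.3f}, "
      f"per-mode cosine {expect['mode_mdcc']:.3f}")

dcc = mdcc.dcc_atom_pair(traj, 0, 1)
print(f"measured DCC(1,2) = {dcc:.3f}   <- diluted by the drift")

models = mdcc.fit_all_atoms(traj, mdcc.FitConfig(seed=42))
for m in models:
    weights = ", ".join(f"{g.weight:.3f}" for g in m.modes)
    print(f"particle {m.atom_id + 1}: {m.n_modes} mode(s), weights [{weights}]")

table = mdcc.all_pairs(traj, models)
for row in table.itertuples():
    status = "omitted (too few co-occurrences)" if row.omitted else \
        f"mDCC = {row.mdcc:.3f}"
    print(f"mode pair (k{row.k + 1}, l{row.l + 1}): mass {row.mass:6.1f}  {status}")

live = table[~table["omitted"]]
print(f"-> every surviving mode pair ({len(live)}) is ~0.97 while the "
      f"global DCC is {dcc:.2f}: the correlation was hidden by the drift.")
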