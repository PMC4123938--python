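"""Simulate a gappy sensor log and impute a gap-free track with the CTCRW.

Generates two hours of a hen-like trajectory in the furnished 6 m x 4.5 m
room, polls it every 8 s with 20% dropout and 0.25 m Gaussian position
noise, fits the continuous-time correlated random walk by maximum
likelihood, and smooths onto a regular 8-s grid.  The printed numbers are
the fitted movement parameters (velocity decay beta, noise intensity
sigma, measurement SD tau) and the size of the imputed track: the grid is
gap-free even though ~20% of the polls were lost.
"""

import numpy as np

import coopgis as cg

room = cg.default_room()
spec = cg.SimulationSpec(duration=2 * 3600.0, seed=7)
track, fixes, _, _ = cg.simulate_animal(spec, room, animal_id="H01")
n_polls = int(spec.duration / spec.poll_interval) + 1
print(f"simulated {n_polls} polls -> {len(fixes)} fixes retained "
      f"({1 - len(fixes) / n_polls:.0%} lost)")

fit = cg.fit_ctcrw(fixes)
p = fit.params
print(f"fitted CTCRW: beta={p.beta:.3f}/s sigma={p.sigma:.3f} m s^-1.5 "
      f"tau={p.tau:.3f} m  (loglik {fit.report.loglik:.1f})")

states = cg.impute_track(fixes, p, grid_interval=8.0, room=room)
rmse = np.sqrt(np.mean(
    (np.array([[s.mean[0], s.mean[2]] for s in states])
     - track.position_at(np.array([s.t for s in states]))) ** 2
))
print(f"imputed {len(states)} grid states; RMSE vs ground truth {rmse:.3f} m")
print("gap-free: every 8-s slot between first and last fix has an estimate.")
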