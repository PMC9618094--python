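"""Recover the agent's memory-noise parameter from its behaviour.

With an isotropic 2-D Gaussian memory corruption of per-axis SD sigma, the
distance between the believed and true locations is Rayleigh(sigma), whose
mean is sigma * sqrt(pi/2) ~= 1.2533 sigma. Because the agent walks to its
believed spot and places there, the mean placement error recovers that
closed form.
"""

import math

import numpy as np

from mmnav import AgentParams, default_environment
from mmnav.agents import simulate_test_batch

env = default_environment()
sigmas = [1.0, 2.0, 4.0, 8.0]
means = []
print("sigma   mean placement error   sigma*sqrt(pi/2)   ratio")
for i, sigma in enumerate(sigmas):
    tab = simulate_test_batch(env, "gold_bar", AgentParams(memory_sd=sigma),
                              n=2000, seed=100 + i)
    mean = tab["placement_error"].mean()
    want = sigma * math.sqrt(math.pi / 2)
    means.append(mean)
    print(f"{sigma:5.1f}   {mean:20.3f}   {want:16.3f}   {mean / want:.4f}")

slope = np.polyfit(sigmas, means, 1)[0]
print(f"\nregression slope of mean error on sigma: {slope:.4f} "
      f"(Rayleigh coefficient sqrt(pi/2) = {math.sqrt(math.pi / 2):.4f})")
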