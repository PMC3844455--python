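# Traveling front with purely excitatory (class A) kernels,
# two transmission speeds and two feedback delays.
task = "speed"
seed = 0

[model]
alpha = 1.0
beta = 0.1
theta = 0.2

[kernel_k]
family = "difference_of_exponentials"
s = 1.0
r = 0.0
rho = 1.0

[kernel_w]
family = "single_exponential"
sigma = 1.0

[speeds]
atoms = [5.0, 10.0]
weights = [0.5, 0.5]

[delays]
atoms = [0.1, 0.2]
weights = [0.5, 0.5]

[simulation]
L = 60.0
n_cells = 600
dt = 0.02
t_end = 40.0
ic = "perturbed_front"
noise_amplitude = 0.025
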