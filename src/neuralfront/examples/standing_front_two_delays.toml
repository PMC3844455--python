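# Standing front with inverted-Mexican-hat (class C) feedback and a
# two-point feedback delay distribution (mean delay 1.95).
task = "simulate"
seed = 0

[model]
alpha = 0.0
beta = 1.0
theta = 0.5

[kernel_k]
family = "single_exponential"
sigma = 1.0

[kernel_w]
# W(x) = (exp(-|x|) - 4.0*exp(-10.0*|x|)) / 1.2
family = "difference_of_exponentials"
s = 1.0
r = 0.4
rho = 10.0

[speeds]
atoms = [5.0]
weights = [1.0]

[delays]
atoms = [1.3, 2.6]
weights = [0.5, 0.5]

[simulation]
L = 60.0
n_cells = 600
dt = 0.02
t_end = 80.0
ic = "step"

[options]
probe_x = 32.0
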