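"""Frozen per-preset initial conditions: the resting state of each default
parameterization after 100 paced beats at 1 Hz (dt = 0.02 ms), regenerated
with ``scripts/freeze_initial_states.py``."""

# state order:
# v, m, h, j, mL, hL, d, f_gate, r_to, s_to, xr1, xr2, xs, xf, c_d, b_d, c_sl, b_sl, c_c, b_c, c_s, b_s, c_n, r

INITIAL_STATES: dict[str, list[float]] = {
    "adult": [
        -8.1690957675e+01, 3.6115649189e-03, 6.3441968048e-01, 6.3413799063e-01,
        6.2408395163e-04, 3.0529205593e-01, 3.6234894308e-05, 9.9965501605e-01,
        4.3593096220e-08, 9.9999561750e-01, 3.8313162277e-04, 4.3465515579e-01,
        4.1607479437e-03, 2.0242950497e-01, 7.3709740758e-05, 1.0978996357e-02,
        1.1460473499e-03, 2.4306382491e-02, 4.4384838874e-05, 4.9460827683e-03,
        1.6203532195e-01, 4.9895060200e+00, 2.3031115817e-01, 9.7992950401e-01
    ],
    "hipsc": [
        -7.9068993563e+01, 6.2013952389e-03, 5.4462067966e-01, 5.9095722630e-01,
        1.0265669269e-03, 2.8597777032e-01, 5.1371281621e-05, 9.9925337924e-01,
        6.6956278791e-08, 9.9999274200e-01, 4.8974726037e-04, 4.0811607309e-01,
        5.0015010572e-03, 1.8731142628e-01, 7.4842325609e-05, 3.9786280878e-02,
        1.6048375688e-04, 9.1447468539e-03, 2.6760061176e-05, 7.2798644134e-03,
        9.4980668769e-02, 7.5883730236e+00, 1.5871779712e-01, 9.8254244530e-01
    ],
}
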