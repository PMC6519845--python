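"""Numerical verification of the cancellation theory.

Builds a Poisson neural drive and a biphasic action-potential template,
then verifies the three analytical statements: the drive/EMG_nc
cross-correlation identity, its spectral counterpart, and the lag-wise
ordering showing the no-cancellation EMG is never the worse estimator
of the drive.
"""
import numpy as np

from emgcancel import (TheoryCase, make_poisson_drive, verify_eq6,
                       verify_eq7, verify_eq10)

FS = 1000.0
t = np.arange(-8, 9)
template = t * np.exp(-(t / 3.0) ** 2)          # biphasic, zero mean
drive = make_poisson_drive(rate=40.0, duration=120.0, fs=FS, seed=0)
case = TheoryCase(drive=drive, template=template, fs=FS)

r6 = verify_eq6(case, tol=0.05)
print(f"cross-correlation identity: pass={r6.passed} "
      f"(rel. sup-norm discrepancy {r6.discrepancy:.4f})")

r7 = verify_eq7(case)
print(f"cross-spectrum identity:    pass={r7.passed} "
      f"(corr(EMG_nc, drive) = {r7.detail['rho']:.3f} < 1)")

r10 = verify_eq10(case)
print(f"estimator ordering:         pass={r10.passed} "
      f"(min margin {r10.detail['margin'].min():.2e} >= 0)")
print("The rectified action potential low-passes the drive, so even the")
print("idealized no-cancellation EMG is an imperfect — though always the")
print("better — estimator of the neural drive.")
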