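# Outcome phrases mapping to the regulatory seriousness categories:
# death, life-threatening, hospitalisation, disability, congenital anomaly.
death
deaths
died
fatal
fatality
life-threatening
hospitalisation
hospitalization
hospitalised
hospitalized
disability
incapacity
congenital anomaly
birth defect
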