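e.g.
i.e.
etc.
vs.
ca.
cf.
dr.
mr.
mrs.
fig.
figs.
eq.
eqs.
al.
no.
nos.
approx.
resp.
sec.
st.
wt.
vol.
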