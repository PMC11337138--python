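of
to
an
the
de
du
des
le
la
les
un
une
et
en
dans
pour
par
avec
sur
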