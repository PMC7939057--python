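; Starter politics vocabulary (run input in production; bundled for tests
; and the synthetic generator).
politics
political
politician
government
congress
senate
senator
parliament
president
presidential
election
elections
vote
voting
voter
ballot
campaign
democrat
democrats
republican
republicans
liberal
conservative
policy
policies
legislation
law
laws
governor
mayor
minister
prime minister
diplomat
diplomacy
treaty
referendum
impeachment
lobbying
constitution
supreme court
white house
capitol
administration
regime
coalition
partisan
geopolitics
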