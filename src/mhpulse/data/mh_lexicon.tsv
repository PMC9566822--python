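# Representative mental-health lexicon, organized into the four symptom
# subgroups (anxiety, depression, insomnia, addiction).  This is a working
# stand-in list: the classifiers take the lexicon as input, so a site-specific
# curated list can be dropped in without code changes.
# Format: term<TAB>subgroup   (lower case; multi-word phrases allowed;
# a term may appear on several lines to map to several subgroups)
anxiety	anxiety
anxious	anxiety
panic	anxiety
panic attack	anxiety
panic attacks	anxiety
worried	anxiety
worrying	anxiety
nervous	anxiety
fearful	anxiety
afraid	anxiety
scared	anxiety
stressed	anxiety
stressed out	anxiety
overwhelmed	anxiety
dread	anxiety
restless	anxiety
uneasy	anxiety
phobia	anxiety
on edge	anxiety
jittery	anxiety
apprehensive	anxiety
freaking out	anxiety
terrified	anxiety
social anxiety	anxiety
anxiety attack	anxiety
depression	depression
depressed	depression
depressing	depression
hopeless	depression
hopelessness	depression
worthless	depression
miserable	depression
despair	depression
lonely	depression
loneliness	depression
sorrowful	depression
crying all day	depression
empty inside	depression
self harm	depression
self-harm	depression
suicidal	depression
suicide	depression
feeling numb	depression
grieving	depression
heartbroken	depression
burnout	depression
burned out	depression
no motivation	depression
cant get out of bed	depression
low mood	depression
insomnia	insomnia
sleepless	insomnia
sleeplessness	insomnia
cant sleep	insomnia
can't sleep	insomnia
cannot sleep	insomnia
sleep deprived	insomnia
sleep deprivation	insomnia
awake all night	insomnia
no sleep	insomnia
up all night	insomnia
nightmares	insomnia
tossing and turning	insomnia
sleep problems	insomnia
trouble sleeping	insomnia
restless night	insomnia
wide awake	insomnia
addiction	addiction
addicted	addiction
alcoholic	addiction
alcoholism	addiction
substance abuse	addiction
overdose	addiction
relapse	addiction
relapsed	addiction
withdrawal symptoms	addiction
drug abuse	addiction
binge drinking	addiction
chain smoking	addiction
opioid	addiction
opioids	addiction
gambling addiction	addiction
drinking problem	addiction
drinking too much	addiction
getting high	addiction
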