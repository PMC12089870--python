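# First-name gazetteer (public-domain common given names).
# Curated to avoid ordinary English words and medication lookalikes.
aaron
abigail
adam
adrian
aisha
alan
albert
alexander
alice
alicia
amanda
amelia
andrea
andrew
angela
anita
anna
anthony
antonio
anya
arthur
ashley
audrey
barbara
benjamin
bernard
beth
betty
beverly
bonnie
bradley
brenda
brian
bruce
calvin
cameron
carl
carla
carmen
carol
caroline
catherine
cecilia
charles
charlotte
cheryl
christina
christopher
cindy
claire
clara
clarence
connie
craig
cynthia
dale
daniel
danielle
darlene
david
deborah
denise
dennis
derek
diana
diane
dolores
donald
donna
doris
dorothy
douglas
edith
edward
eleanor
elena
elizabeth
ellen
emily
emma
eric
erica
ernest
esther
ethel
eugene
evelyn
felix
fernando
florence
frances
francis
frank
frederick
gabriel
gary
geraldine
gerald
gilbert
gladys
glenn
gloria
gordon
gregory
gretchen
harold
harriet
harvey
hazel
hector
helen
henry
herbert
howard
irene
isaac
isabel
jacob
jacqueline
james
jane
janet
janice
jason
jean
jeffrey
jennifer
jeremy
jerome
jessica
joan
joanne
john
jonathan
jorge
jose
joseph
josephine
joshua
joyce
juan
juanita
judith
julia
julian
juliet
karen
katherine
kathleen
keith
kelly
kenneth
kevin
kristen
larry
laura
lawrence
leonard
leslie
lillian
linda
lisa
lloyd
lois
loretta
lorraine
louis
louise
lucia
lucille
lucy
luis
lydia
lynn
mabel
marcia
marcus
margaret
maria
marie
marilyn
marion
marjorie
marlene
martha
martin
marvin
mary
matthew
maureen
maxine
megan
melissa
michael
michelle
mildred
miriam
monica
nancy
naomi
natalie
nathan
nicholas
nicole
nora
norma
norman
olivia
oscar
pamela
patricia
patrick
paul
paula
pauline
pedro
peggy
peter
philip
phyllis
rachel
ralph
ramona
raymond
rebecca
regina
renee
ricardo
richard
rita
robert
roberta
roberto
rodney
roger
ronald
rosa
rosalie
rose
rosemary
roy
russell
ruth
samantha
samuel
sandra
sarah
scott
sharon
sheila
shirley
sidney
simon
sofia
stanley
stephanie
stephen
steven
susan
sylvia
tamara
teresa
theodore
thelma
thomas
timothy
tracy
valerie
vanessa
vera
vernon
veronica
victor
victoria
vincent
viola
virginia
vivian
walter
wanda
wayne
wendy
wesley
william
willie
yolanda
yvonne
zachary
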