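; Starter entertainment vocabulary (run input in production; bundled for
; tests and the synthetic generator).
entertainment
movie
movies
film
films
cinema
theater
theatre
music
musician
concert
album
song
songs
singer
band
celebrity
hollywood
netflix
streaming
series
sitcom
drama
comedy
comedian
festival
gaming
videogame
esports
playlist
podcast
box office
premiere
trailer
blockbuster
sequel
actor
actress
grammy
oscars
tv show
anime
karaoke
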